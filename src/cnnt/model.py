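"""The CNNT U-net: convolutional attention over the frame axis inside a
transformer cell, arranged as a two-down/two-up U-net with a long additive
skip from input to output.

The canonical feature tensor is 5-axis ``[B, T, C, H, W]`` (batch, frames,
channels, height, width).  Each frame is embedded by shared 2D convolutions;
soft attention then acts across the frame (Z or time) axis, so the model
captures long-range correlation along depth/time at convolutional cost.
All convolutions are 2D with 3x3 kernels; spatial down/upsampling by factor
2 doubles/halves the channel count (e.g. 32 -> 64 -> 128 -> 64 -> 32 for the
default two-level configuration).

With the output projection of every residual branch and the final post-conv
zero-initialised, a freshly built network is exactly the identity map — the
long additive skip means training learns a residual correction, which keeps
early SSIM-loss optimisation stable.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["CNNTConfig", "CNNAttention", "CNNMixer", "CNNTCell",
           "DownsampleBlock", "UpsampleBlock", "CNNTUnet",
           "count_parameters", "ConfigError"]


class ConfigError(ValueError):
    """Inconsistent architecture hyperparameters."""


@dataclasses.dataclass
class CNNTConfig:
    """Architecture hyperparameters.

    ``base_channels=32`` and ``cells_per_block=4`` with two down and two up
    levels give the full-size model; the desk-scale tests use a reduced
    configuration (the architecture is identical, only widths shrink).
    """

    in_channels: int = 1
    base_channels: int = 32
    n_levels_down: int = 2
    n_levels_up: int = 2
    cells_per_block: int = 4
    n_heads: int = 2
    kernel: tuple[int, int] = (3, 3)
    norm_kind: str = "instance"
    activation: str = "gelu"

    def __post_init__(self):
        self.kernel = tuple(self.kernel)
        if self.base_channels % self.n_heads:
            raise ConfigError(
                f"base_channels {self.base_channels} not divisible by "
                f"n_heads {self.n_heads}")
        if self.n_levels_up != self.n_levels_down:
            raise ConfigError("n_levels_up must equal n_levels_down")
        if self.kernel[0] % 2 == 0 or self.kernel[1] % 2 == 0:
            raise ConfigError(f"kernel must be odd in both dims, got {self.kernel}")
        if self.norm_kind != "instance":
            raise ConfigError(f"unsupported norm_kind {self.norm_kind!r}")
        if self.activation != "gelu":
            raise ConfigError(f"unsupported activation {self.activation!r}")

    @property
    def spatial_divisor(self) -> int:
        return 2 ** self.n_levels_down

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kernel"] = list(self.kernel)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CNNTConfig":
        return cls(**d)


def _check_feature_tensor(x: Tensor) -> tuple[int, int, int, int, int]:
    if x.ndim != 5:
        raise ValueError(f"expected [B, T, C, H, W] feature tensor, got shape {x.shape}")
    return x.shape


def _merge_frames(x: Tensor) -> Tensor:
    B, T, C, H, W = x.shape
    return x.reshape(B * T, C, H, W)


def _split_frames(x: Tensor, B: int, T: int) -> Tensor:
    _, C, H, W = x.shape
    return x.reshape(B, T, C, H, W)


class CNNAttention(nn.Module):
    """Soft attention across the frame axis with convolutional embeddings.

    Key, query and value feature maps are computed per frame by 2D 3x3
    convolutions shared across frames, then flattened; for each head the
    attention score between frames t and t' is the scaled dot product of the
    flattened query and key maps, softmaxed over key frames.  The attended
    values are concatenated over heads and fused by a 1x1 output convolution
    (zero-initialised so the enclosing residual starts as identity).

    With shared per-frame convolutions and no positional encoding the
    operation is equivariant to permutations of the frame axis.
    """

    def __init__(self, channels: int, n_heads: int = 2, kernel=3,
                 rng: np.random.Generator | None = None, zero_init_out: bool = True):
        super().__init__()
        if channels % n_heads:
            raise ConfigError(f"channels {channels} not divisible by n_heads {n_heads}")
        self.channels = channels
        self.n_heads = n_heads
        self.head_channels = channels // n_heads
        self.conv_q = nn.Conv2d(channels, channels, kernel, rng=rng)
        self.conv_k = nn.Conv2d(channels, channels, kernel, rng=rng)
        self.conv_v = nn.Conv2d(channels, channels, kernel, rng=rng)
        self.conv_out = nn.Conv2d(channels, channels, 1, rng=rng, zero_init=zero_init_out)
        self.last_attention: np.ndarray | None = None
        self.capture_attention = False

    def forward(self, x: Tensor, return_map: bool = False):
        B, T, C, H, W = _check_feature_tensor(x)
        nh, Ch = self.n_heads, self.head_channels
        flat = _merge_frames(x)
        q = self.conv_q(flat)  # [B*T, C, H, W]
        k = self.conv_k(flat)
        v = self.conv_v(flat)
        # -> [B, heads, T, Ch*H*W]
        def heads(z: Tensor) -> Tensor:
            return z.reshape(B, T, nh, Ch * H * W).swapaxes(1, 2)
        qh, kh, vh = heads(q), heads(k), heads(v)
        scale = 1.0 / math.sqrt(Ch * H * W)
        scores = (qh @ kh.swapaxes(-1, -2)) * scale   # [B, heads, T, T]
        attn = scores.softmax(axis=-1)
        out = attn @ vh                                # [B, heads, T, Ch*H*W]
        out = out.swapaxes(1, 2).reshape(B * T, C, H, W)
        out = self.conv_out(out)
        out = _split_frames(out, B, T)
        if self.capture_attention:
            self.last_attention = attn.data.copy()
        if return_map:
            return out, attn.data.copy()
        return out


class CNNMixer(nn.Module):
    """Per-frame channel mixer: two 3x3 convolutions with a GELU between,
    expanding channels by 2x then projecting back (last conv zero-initialised
    for residual identity at build time)."""

    def __init__(self, channels: int, expansion: int = 2, kernel=3,
                 rng: np.random.Generator | None = None, zero_init_out: bool = True):
        super().__init__()
        hidden = channels * expansion
        self.conv1 = nn.Conv2d(channels, hidden, kernel, rng=rng)
        self.conv2 = nn.Conv2d(hidden, channels, kernel, rng=rng, zero_init=zero_init_out)

    def forward(self, x: Tensor) -> Tensor:
        B, T, C, H, W = _check_feature_tensor(x)
        y = _merge_frames(x)
        y = self.conv2(self.conv1(y).gelu())
        return _split_frames(y, B, T)


class CNNTCell(nn.Module):
    """Pre-norm transformer cell with convolutional attention and mixer:

        y   = x + attention(norm(x))
        out = y + mixer(norm(y))
    """

    def __init__(self, channels: int, n_heads: int = 2, kernel=3,
                 rng: np.random.Generator | None = None, zero_init_out: bool = True):
        super().__init__()
        self.norm1 = nn.InstanceNorm2d(channels)
        self.attention = CNNAttention(channels, n_heads, kernel, rng=rng,
                                      zero_init_out=zero_init_out)
        self.norm2 = nn.InstanceNorm2d(channels)
        self.mixer = CNNMixer(channels, kernel=kernel, rng=rng,
                              zero_init_out=zero_init_out)

    def _norm(self, norm: nn.InstanceNorm2d, x: Tensor) -> Tensor:
        B, T, C, H, W = x.shape
        return _split_frames(norm(_merge_frames(x)), B, T)

    def forward(self, x: Tensor) -> Tensor:
        y = x + self.attention(self._norm(self.norm1, x))
        return y + self.mixer(self._norm(self.norm2, y))


class DownsampleBlock(nn.Module):
    """``cells_per_block`` CNNT cells followed by a stride-2 3x3 convolution
    that doubles channels and halves H and W.  Returns (downsampled, skip)
    where skip is the cell output at the incoming resolution."""

    def __init__(self, channels: int, n_cells: int, n_heads: int, kernel=3,
                 rng: np.random.Generator | None = None, zero_init_out: bool = True):
        super().__init__()
        self.cells = nn.Sequential(*[
            CNNTCell(channels, n_heads, kernel, rng=rng, zero_init_out=zero_init_out)
            for _ in range(n_cells)])
        self.down = nn.Conv2d(channels, channels * 2, kernel, stride=2, rng=rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        B, T, C, H, W = _check_feature_tensor(x)
        if H % 2 or W % 2:
            raise ValueError(
                f"spatial size ({H}, {W}) not even; pad the input before downsampling")
        skip = self.cells(x)
        down = _split_frames(self.down(_merge_frames(skip)), B, T)
        return down, skip


class UpsampleBlock(nn.Module):
    """2x nearest-neighbour upsampling + conv to half the channels, channel
    concatenation with the skip from the matching down level, a 1x1 fuse back
    to half channels, then ``cells_per_block`` CNNT cells."""

    def __init__(self, channels: int, n_cells: int, n_heads: int, kernel=3,
                 rng: np.random.Generator | None = None, zero_init_out: bool = True):
        super().__init__()
        if channels % 2:
            raise ConfigError(f"upsample block needs even channels, got {channels}")
        half = channels // 2
        self.up_conv = nn.Conv2d(channels, half, kernel, rng=rng)
        self.fuse = nn.Conv2d(channels, half, 1, rng=rng)
        self.cells = nn.Sequential(*[
            CNNTCell(half, n_heads, kernel, rng=rng, zero_init_out=zero_init_out)
            for _ in range(n_cells)])
        self.in_channels = channels

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        B, T, C, H, W = _check_feature_tensor(x)
        Bs, Ts, Cs, Hs, Ws = _check_feature_tensor(skip)
        if (Bs, Ts) != (B, T) or Cs != C // 2 or (Hs, Ws) != (2 * H, 2 * W):
            raise ValueError(
                f"skip shape {skip.shape} incompatible with upsample input {x.shape}: "
                f"expected channels {C // 2} and spatial ({2 * H}, {2 * W})")
        y = self.up_conv(_merge_frames(x).upsample2x())
        y = nn.concatenate([y, _merge_frames(skip)], axis=1)
        y = self.fuse(y)
        return self.cells(_split_frames(y, B, T))


class CNNTUnet(nn.Module):
    """The full denoiser: pre-conv channel uplift, U-net backbone of CNNT
    blocks, post-conv back to the input channel count, and a long additive
    skip so the network predicts a residual correction.

    ``init="identity"`` (default) zero-initialises the post-conv and every
    residual output projection, making the fresh network the exact identity;
    ``init="random"`` initialises everything with fan-in scaling.
    """

    def __init__(self, cfg: CNNTConfig | None = None,
                 rng: np.random.Generator | int | None = None,
                 init: str = "identity"):
        super().__init__()
        self.cfg = cfg = cfg or CNNTConfig()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        if init not in ("identity", "random"):
            raise ConfigError(f"unknown init {init!r}")
        zero = init == "identity"
        k = cfg.kernel
        self.pre_conv = nn.Conv2d(cfg.in_channels, cfg.base_channels, k, rng=rng)
        ch = cfg.base_channels
        self.down_blocks = []
        for i in range(cfg.n_levels_down):
            blk = DownsampleBlock(ch, cfg.cells_per_block, cfg.n_heads, k,
                                  rng=rng, zero_init_out=zero)
            setattr(self, f"down{i}", blk)
            self.down_blocks.append(blk)
            ch *= 2
        self.up_blocks = []
        for i in range(cfg.n_levels_up):
            blk = UpsampleBlock(ch, cfg.cells_per_block, cfg.n_heads, k,
                                rng=rng, zero_init_out=zero)
            setattr(self, f"up{i}", blk)
            self.up_blocks.append(blk)
            ch //= 2
        self.post_conv = nn.Conv2d(ch, cfg.in_channels, k, rng=rng, zero_init=zero)

    # ------------------------------------------------------------------
    def forward(self, x: Tensor) -> Tensor:
        B, T, C, H, W = _check_feature_tensor(x)
        if C != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {C}")
        d = self.cfg.spatial_divisor
        if H % d or W % d:
            raise ValueError(
                f"spatial size ({H}, {W}) not divisible by {d}; reflect-pad first "
                f"(see cnnt.evaluation.infer_volume)")
        y = _split_frames(self.pre_conv(_merge_frames(x)), B, T)
        skips = []
        for blk in self.down_blocks:
            y, skip = blk(y)
            skips.append(skip)
        for blk in self.up_blocks:
            y = blk(y, skips.pop())
        y = _split_frames(self.post_conv(_merge_frames(y)), B, T)
        return x + y

    # ------------------------------------------------------------------
    def attention_cells(self) -> list[tuple[str, int, CNNAttention]]:
        """All attention modules tagged by (level id, cell index)."""
        out = []
        for i, blk in enumerate(self.down_blocks):
            for j, cell in enumerate(blk.cells.layers):
                out.append((f"down{i}", j, cell.attention))
        for i, blk in enumerate(self.up_blocks):
            for j, cell in enumerate(blk.cells.layers):
                out.append((f"up{i}", j, cell.attention))
        return out


def count_parameters(cfg_or_model: CNNTConfig | CNNTUnet) -> int:
    """Total trainable parameter count (deterministic for a given config)."""
    model = (cfg_or_model if isinstance(cfg_or_model, CNNTUnet)
             else CNNTUnet(cfg_or_model, rng=0))
    return int(sum(p.size for p in model.parameters()))
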