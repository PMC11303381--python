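"""Full-volume inference and evaluation protocols.

Large acquisitions (e.g. 100 x 1200 x 1200) do not fit through the network
in one piece on desk hardware, so inference tiles the volume with overlap
and blends tile outputs with a strictly positive cosine taper; accumulated
weights are normalised voxelwise, so the blend weights form an exact
partition of unity and interior voxels are insensitive to the tiling.

The multi-average protocol probes robustness to input SNR: from a stack of
n_rep repeated acquisitions of one field of view, Avg n (mean of the first n
repeats) gives a family of inputs with increasing SNR; Avg n_rep serves as
the ground truth and PSNR/SSIM3D are recorded before and after denoising
for each n.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from . import nn
from .data_io import ImageVolume, NormalizationSpec, denormalize_volume, normalize_volume
from .metrics import SSIMParams, psnr, ssim3d
from .model import CNNTUnet
from .synthetic import RepeatStack, running_average
from .training import Checkpoint, build_model

__all__ = ["TilingSpec", "RobustnessRow", "RobustnessTable", "infer_volume",
           "multi_average_experiment", "extract_attention_maps"]


@dataclasses.dataclass
class TilingSpec:
    """Tile geometry for sliding-window inference.

    ``tile`` / ``overlap`` are (frames, h, w); spatial overlap defaults to a
    quarter tile, frame overlap to 2 frames (attention only spans frames
    inside one tile, so overlap mitigates temporal edge effects).
    """

    tile: tuple[int, int, int] = (8, 128, 128)
    overlap: tuple[int, int, int] | None = None
    blend: str = "cosine-window"   # {"cosine-window", "crop-center"}

    def __post_init__(self):
        self.tile = tuple(self.tile)
        if self.overlap is None:
            self.overlap = (min(2, self.tile[0] - 1),
                            self.tile[1] // 4, self.tile[2] // 4)
        self.overlap = tuple(self.overlap)
        if any(o >= t for o, t in zip(self.overlap, self.tile)):
            raise ValueError(f"overlap {self.overlap} must be < tile {self.tile}")
        if any(o < 0 for o in self.overlap):
            raise ValueError("overlap must be non-negative")
        if self.blend not in ("cosine-window", "crop-center"):
            raise ValueError(f"unknown blend {self.blend!r}")


@dataclasses.dataclass
class RobustnessRow:
    n_avg: int
    psnr_in: float
    psnr_out: float
    ssim3d_in: float
    ssim3d_out: float


@dataclasses.dataclass
class RobustnessTable:
    rows: list[RobustnessRow]

    def __post_init__(self):
        ns = [r.n_avg for r in self.rows]
        if ns != sorted(set(ns)):
            raise ValueError("rows must have strictly increasing n_avg")

    def column(self, name: str) -> list[float]:
        return [getattr(r, name) for r in self.rows]

    def to_csv(self, path) -> None:
        import csv
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["n_avg", "psnr_in", "psnr_out", "ssim3d_in", "ssim3d_out"])
            for r in self.rows:
                writer.writerow([r.n_avg, r.psnr_in, r.psnr_out,
                                 r.ssim3d_in, r.ssim3d_out])


# ----------------------------------------------------------------------

def _tile_positions(size: int, tile: int, overlap: int) -> list[int]:
    if tile >= size:
        return [0]
    step = tile - overlap
    pos = list(range(0, size - tile, step))
    pos.append(size - tile)
    return pos


def _taper(tile: int, overlap: int, blend: str) -> np.ndarray:
    """Strictly positive 1D blend profile: cosine ramps over the overlap."""
    w = np.ones(tile)
    if overlap > 0:
        if blend == "cosine-window":
            ramp = 0.5 - 0.5 * np.cos(math.pi * (np.arange(overlap) + 0.5) / overlap)
        else:  # crop-center: nearly ignore the margins
            ramp = np.full(overlap, 1e-6)
        w[:overlap] = ramp
        w[-overlap:] = ramp[::-1]
    return w


def _resolve(model_or_ckpt) -> tuple[CNNTUnet, NormalizationSpec]:
    if isinstance(model_or_ckpt, Checkpoint):
        return build_model(model_or_ckpt), model_or_ckpt.normalization
    if isinstance(model_or_ckpt, CNNTUnet):
        return model_or_ckpt, NormalizationSpec()
    raise TypeError(f"expected Checkpoint or CNNTUnet, got {type(model_or_ckpt)}")


def infer_volume(model: "Checkpoint | CNNTUnet", vol: ImageVolume,
                 tiling: TilingSpec | None = None,
                 normalization: NormalizationSpec | None = None) -> ImageVolume:
    """Denoise a full volume of arbitrary size.

    Pipeline: normalise -> reflect-pad H/W to the U-net's spatial divisor ->
    overlapped tiled forward passes -> cosine-weighted blend (weights
    normalised to an exact partition of unity) -> crop -> denormalise.
    Tiles larger than the (padded) volume are clamped, so a volume that fits
    one tile reduces to a direct forward pass.  Output shape equals input
    shape.
    """
    net, default_norm = _resolve(model)
    tiling = tiling or TilingSpec()
    d = net.cfg.spatial_divisor
    if any(t % d for t in tiling.tile[1:]):
        raise ValueError(f"tile spatial dims {tiling.tile[1:]} must be divisible by {d}")
    normed, params = normalize_volume(vol, normalization or default_norm)
    v = normed.voxels.astype(np.float32)
    nf, H, W = v.shape
    padH = (-H) % d
    padW = (-W) % d
    if padH or padW:
        v = np.pad(v, ((0, 0), (0, padH), (0, padW)), mode="reflect")
    shape = v.shape
    tile = tuple(min(t, s) for t, s in zip(tiling.tile, shape))
    # keep spatial tile divisible by the U-net factor after clamping
    tile = (tile[0],) + tuple(t - t % d for t in tile[1:])
    overlap = tuple(min(o, t - 1) for o, t in zip(tiling.overlap, tile))
    tapers = [_taper(t, o, tiling.blend) for t, o in zip(tile, overlap)]
    weight = (tapers[0][:, None, None] * tapers[1][None, :, None]
              * tapers[2][None, None, :]).astype(np.float32)
    num = np.zeros(shape, dtype=np.float32)
    den = np.zeros(shape, dtype=np.float32)
    with nn.no_grad():
        for z0 in _tile_positions(shape[0], tile[0], overlap[0]):
            for y0 in _tile_positions(shape[1], tile[1], overlap[1]):
                for x0 in _tile_positions(shape[2], tile[2], overlap[2]):
                    sl = (slice(z0, z0 + tile[0]), slice(y0, y0 + tile[1]),
                          slice(x0, x0 + tile[2]))
                    block = v[sl][None, :, None]          # [1, T, 1, h, w]
                    out = net(nn.Tensor(block)).data[0, :, 0]
                    num[sl] += weight * out
                    den[sl] += weight
    blended = num / den
    blended = blended[:, :H, :W]
    return denormalize_volume(ImageVolume(blended, vol.axis_kind), params)


def multi_average_experiment(model: "Checkpoint | CNNTUnet", stack: RepeatStack,
                             ns: Sequence[int] = (1, 4, 8, 16, 32, 64),
                             tiling: TilingSpec | None = None,
                             normalization: NormalizationSpec | None = None
                             ) -> RobustnessTable:
    """Denoise Avg n for each requested n and score against Avg n_rep.

    ``data_range`` for both metrics is the value range of the ground-truth
    average.  The n = n_rep row scores the ground truth against itself, so
    psnr_in is the infinite-PSNR sentinel there.
    """
    ns = sorted(set(int(n) for n in ns))
    if ns[-1] > stack.n_rep:
        raise ValueError(f"max(ns)={ns[-1]} exceeds n_rep={stack.n_rep}")
    gt = running_average(stack, stack.n_rep)
    data_range = float(gt.voxels.max() - gt.voxels.min())
    sp = SSIMParams(window=7, window_kind="uniform", data_range=data_range)
    rows = []
    for n in ns:
        avg = running_average(stack, n)
        out = infer_volume(model, avg, tiling, normalization)
        rows.append(RobustnessRow(
            n_avg=n,
            psnr_in=psnr(avg, gt, data_range),
            psnr_out=psnr(out, gt, data_range),
            ssim3d_in=ssim3d(avg, gt, sp),
            ssim3d_out=ssim3d(out, gt, sp),
        ))
    return RobustnessTable(rows)


def extract_attention_maps(model: "Checkpoint | CNNTUnet", vol: ImageVolume,
                           tiling: TilingSpec | None = None,
                           normalization: NormalizationSpec | None = None
                           ) -> list[tuple[str, int, np.ndarray]]:
    """Frame-interaction attention maps from every CNNT cell.

    Runs one forward pass (on the first tile if the volume exceeds the tile
    size) with attention capture enabled and returns ``(level_id, cell_id,
    map)`` triples, one ``[B, heads, T, T]`` row-stochastic map per cell,
    ordered down the encoder then up the decoder.
    """
    net, default_norm = _resolve(model)
    tiling = tiling or TilingSpec()
    normed, _ = normalize_volume(vol, normalization or default_norm)
    v = normed.voxels.astype(np.float32)
    d = net.cfg.spatial_divisor
    tile = tuple(min(t, s) for t, s in zip(tiling.tile, v.shape))
    v = v[:tile[0], :tile[1], :tile[2]]
    padH = (-v.shape[1]) % d
    padW = (-v.shape[2]) % d
    if padH or padW:
        v = np.pad(v, ((0, 0), (0, padH), (0, padW)), mode="reflect")
    cells = net.attention_cells()
    for _, _, attn in cells:
        attn.capture_attention = True
        attn.last_attention = None
    try:
        with nn.no_grad():
            net(nn.Tensor(v[None, :, None]))
        return [(level, idx, attn.last_attention) for level, idx, attn in cells]
    finally:
        for _, _, attn in cells:
            attn.capture_attention = False
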