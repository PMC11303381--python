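"""Architecture contracts: attention semantics against a brute-force oracle,
residual/identity behaviour, U-net shape schedule, equivariances."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cnnt import nn
from cnnt.nn import Tensor
from cnnt.model import (CNNAttention, CNNMixer, CNNTCell, CNNTConfig, CNNTUnet,
                        ConfigError, DownsampleBlock, UpsampleBlock,
                        count_parameters)


def brute_force_attention(attn: CNNAttention, x: np.ndarray) -> np.ndarray:
    """Explicit nested loops over frames, heads, channels and pixels."""
    B, T, C, H, W = x.shape
    nh, Ch = attn.n_heads, attn.head_channels

    def conv_frame(w, b, xt):
        Co, Ci, kh, kw = w.shape
        p = kh // 2
        xp = np.pad(xt, ((0, 0), (p, p), (p, p)))
        out = np.zeros((Co, H, W))
        for co in range(Co):
            for c in range(Ci):
                for i in range(kh):
                    for j in range(kw):
                        out[co] += w[co, c, i, j] * xp[c, i:i + H, j:j + W]
            out[co] += b[co]
        return out

    def embed(conv):
        return np.stack([[conv_frame(conv.weight.data, conv.bias.data, x[b, t])
                          for t in range(T)] for b in range(B)])

    q, k, v = embed(attn.conv_q), embed(attn.conv_k), embed(attn.conv_v)
    attended = np.zeros((B, T, C, H, W))
    for b in range(B):
        for h in range(nh):
            ch = slice(h * Ch, (h + 1) * Ch)
            scores = np.zeros((T, T))
            for t in range(T):
                for t2 in range(T):
                    scores[t, t2] = np.sum(q[b, t, ch] * k[b, t2, ch]) \
                        / math.sqrt(Ch * H * W)
            e = np.exp(scores - scores.max(axis=1, keepdims=True))
            A = e / e.sum(axis=1, keepdims=True)
            for t in range(T):
                for t2 in range(T):
                    attended[b, t, ch] += A[t, t2] * v[b, t2, ch]
    out = np.zeros_like(attended)
    w1, b1 = attn.conv_out.weight.data, attn.conv_out.bias.data
    for b in range(B):
        for t in range(T):
            out[b, t] = np.einsum("oc,chw->ohw", w1[:, :, 0, 0],
                                  attended[b, t]) + b1[:, None, None]
    return out


@pytest.mark.parametrize("shape,heads", [((1, 3, 4, 5, 5), 1),
                                         ((2, 4, 4, 6, 6), 2)])
def test_attention_matches_brute_force(rng, shape, heads):
    attn = CNNAttention(shape[2], n_heads=heads,
                        rng=np.random.default_rng(1), zero_init_out=False)
    x = rng.normal(size=shape).astype(np.float32)
    out, amap = attn(Tensor(x), return_map=True)
    ref = brute_force_attention(attn, x)
    assert np.allclose(out.data, ref, atol=1e-5)
    assert np.allclose(amap.sum(axis=-1), 1.0, atol=1e-5)
    assert (amap >= 0).all() and (amap <= 1).all()


def test_attention_single_frame_is_trivial(rng):
    attn = CNNAttention(4, n_heads=2, rng=np.random.default_rng(0),
                        zero_init_out=False)
    x = rng.normal(size=(2, 1, 4, 6, 6)).astype(np.float32)
    _, amap = attn(Tensor(x), return_map=True)
    assert np.allclose(amap, 1.0)


def test_attention_frame_permutation_equivariance(rng):
    attn = CNNAttention(4, n_heads=2, rng=np.random.default_rng(3),
                        zero_init_out=False)
    x = rng.normal(size=(1, 5, 4, 6, 6)).astype(np.float32)
    perm = np.array([3, 0, 4, 1, 2])
    out = attn(Tensor(x)).data
    out_perm = attn(Tensor(x[:, perm])).data
    assert np.allclose(out[:, perm], out_perm, atol=1e-5)


def test_attention_rejects_bad_heads():
    with pytest.raises(ConfigError):
        CNNAttention(6, n_heads=4)


def test_mixer_shape_and_channel_coupling(rng):
    mixer = CNNMixer(8, rng=np.random.default_rng(0), zero_init_out=False)
    x = rng.normal(size=(1, 4, 8, 16, 16)).astype(np.float32)
    y = mixer(Tensor(x)).data
    assert y.shape == x.shape
    # perturbing one input channel must reach every output channel
    x2 = x.copy()
    x2[:, :, 3] += 0.5
    dy = np.abs(mixer(Tensor(x2)).data - y).sum(axis=(0, 1, 3, 4))
    assert (dy > 0).all()


def test_cell_residual_identity_at_build(rng):
    cell = CNNTCell(8, n_heads=2, rng=np.random.default_rng(0), zero_init_out=True)
    x = rng.normal(size=(2, 3, 8, 8, 8)).astype(np.float32)
    assert np.array_equal(cell(Tensor(x)).data, x)


def test_cell_shape_preservation(rng):
    cell = CNNTCell(8, n_heads=2, rng=np.random.default_rng(0), zero_init_out=False)
    x = rng.normal(size=(2, 8, 8, 16, 16)).astype(np.float32)
    assert cell(Tensor(x)).shape == x.shape


def test_down_up_block_schedule(rng):
    g = np.random.default_rng(0)
    down = DownsampleBlock(8, n_cells=1, n_heads=2, rng=g)
    x = rng.normal(size=(1, 4, 8, 32, 32)).astype(np.float32)
    y, skip = down(Tensor(x))
    assert y.shape == (1, 4, 16, 16, 16)
    assert skip.shape == x.shape
    up = UpsampleBlock(16, n_cells=1, n_heads=2, rng=g)
    z = up(y, skip)
    assert z.shape == (1, 4, 8, 32, 32)


def test_downsample_rejects_odd_size(rng):
    down = DownsampleBlock(4, 1, 1, rng=np.random.default_rng(0))
    with pytest.raises(ValueError, match="pad"):
        down(Tensor(rng.normal(size=(1, 2, 4, 15, 16)).astype(np.float32)))


def test_upsample_rejects_bad_skip(rng):
    up = UpsampleBlock(8, 1, 1, rng=np.random.default_rng(0))
    x = Tensor(rng.normal(size=(1, 2, 8, 8, 8)).astype(np.float32))
    bad_skip = Tensor(rng.normal(size=(1, 2, 4, 8, 8)).astype(np.float32))
    with pytest.raises(ValueError, match="skip"):
        up(x, bad_skip)


def test_unet_zero_init_is_identity(rng):
    net = CNNTUnet(CNNTConfig(base_channels=8, cells_per_block=2), rng=0)
    x = rng.normal(size=(1, 8, 1, 32, 32)).astype(np.float32)
    assert np.array_equal(net(Tensor(x)).data, x)


def test_unet_channel_schedule_default_config(rng):
    """Default two-level U-net: 32 -> 64 -> 128 -> 64 -> 32 channels."""
    net = CNNTUnet(CNNTConfig(), rng=0)
    assert net.pre_conv.weight.shape[0] == 32
    assert net.down_blocks[0].down.weight.shape[:2] == (64, 32)
    assert net.down_blocks[1].down.weight.shape[:2] == (128, 64)
    assert net.up_blocks[0].up_conv.weight.shape[:2] == (64, 128)
    assert net.up_blocks[1].up_conv.weight.shape[:2] == (32, 64)
    assert net.post_conv.weight.shape[:2] == (1, 32)


def test_unet_accepts_multiple_input_sizes(rng, tiny_cfg):
    net = CNNTUnet(tiny_cfg, rng=0, init="random")
    for shape in [(1, 8, 1, 32, 32), (1, 8, 1, 40, 40), (1, 1, 1, 16, 16),
                  (2, 3, 1, 16, 24)]:
        x = rng.normal(size=shape).astype(np.float32)
        assert net(Tensor(x)).shape == shape


def test_unet_rejects_indivisible_spatial(rng, tiny_cfg):
    net = CNNTUnet(tiny_cfg, rng=0)
    with pytest.raises(ValueError, match="divisible"):
        net(Tensor(rng.normal(size=(1, 2, 1, 15, 16)).astype(np.float32)))


def test_unet_gradient_reaches_every_parameter(rng, tiny_cfg):
    net = CNNTUnet(tiny_cfg, rng=0, init="random")
    x = Tensor(rng.normal(size=(1, 3, 1, 16, 16)).astype(np.float32))
    (net(x) ** 2.0).mean().backward()
    dead = [n for n, p in net.named_parameters()
            if p.grad is None or not np.abs(p.grad).max() > 0]
    assert dead == []


def test_unet_translation_equivariance_on_local_structure(rng, tiny_cfg):
    """Shifting a compactly supported structure by a multiple of the
    downsampling factor shifts the output identically, as long as the
    structure's receptive-field footprint stays away from the borders
    (convolutional inductive bias; whole-frame attention scores are sums,
    hence shift-invariant)."""
    net = CNNTUnet(tiny_cfg, rng=0, init="random")
    # temper the attention logits: equivariance is exact in exact arithmetic,
    # but a saturated softmax amplifies float32 summation-order noise
    for _, _, attn in net.attention_cells():
        attn.conv_q.weight.data *= 0.1
        attn.conv_k.weight.data *= 0.1
    x = np.zeros((1, 2, 1, 48, 48), dtype=np.float32)
    x[0, :, 0, 20:28, 20:28] = rng.normal(size=(2, 8, 8)).astype(np.float32)
    d = 2 * tiny_cfg.spatial_divisor
    shifted = np.roll(x, (d, d), axis=(3, 4))
    y = net(Tensor(x)).data
    y_shift = net(Tensor(shifted)).data
    # borders excluded: zero-padding border responses do not move with the
    # content, and the frame-wide norm couples them weakly into the interior
    m = 12
    err = np.abs((np.roll(y, (d, d), axis=(3, 4)) - y_shift)[..., m:-m, m:-m]).max()
    assert err <= 1e-3 * max(1.0, np.abs(y).max())


def test_count_parameters_deterministic_and_monotone(tiny_cfg):
    n1 = count_parameters(tiny_cfg)
    assert n1 == count_parameters(tiny_cfg)
    bigger = CNNTConfig(in_channels=1, base_channels=8, n_levels_down=1,
                        n_levels_up=1, cells_per_block=1, n_heads=1)
    assert count_parameters(bigger) > n1


def test_count_parameters_hand_tally(tiny_cfg):
    """base 4, one level, one cell per block, one head, 3x3 kernels."""
    def conv(ci, co, k):
        return co * ci * k * k + co

    cell4 = (2 * (4 + 4)            # two instance norms (gamma, beta)
             + 3 * conv(4, 4, 3)    # q, k, v
             + conv(4, 4, 1)        # attention output projection
             + conv(4, 8, 3) + conv(8, 4, 3))   # mixer expand + project
    expected = (conv(1, 4, 3)       # pre-conv uplift
                + cell4 + conv(4, 8, 3)          # down block + strided down
                + conv(8, 4, 3) + conv(8, 4, 1)  # up conv + fuse
                + cell4                           # up block cell
                + conv(4, 1, 3))    # post conv
    assert count_parameters(tiny_cfg) == expected


def test_config_validation():
    with pytest.raises(ConfigError):
        CNNTConfig(base_channels=6, n_heads=4)
    with pytest.raises(ConfigError):
        CNNTConfig(n_levels_down=2, n_levels_up=1)
    with pytest.raises(ConfigError):
        CNNTConfig(kernel=(2, 3))
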