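"""Restoration quality metrics (PSNR, SSIM in 2D and 3D) and the
differentiable SSIM training loss.

PSNR is ``10·log10(data_range² / MSE)`` over all voxels.  SSIM follows the
standard luminance–contrast–structure product with C1=(k1·L)², C2=(k2·L)²:
the training loss uses the canonical 11x11 Gaussian window (sigma 1.5)
applied per frame and averaged over frames; volumetric evaluation (SSIM3D)
uses a 7x7x7 uniform window, with the window depth clamped to the number of
frames for thin stacks.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.ndimage import uniform_filter

from . import nn
from .nn import Tensor
from .data_io import ImageVolume

__all__ = ["SSIMParams", "psnr", "ssim2d", "ssim3d", "ssim_loss", "INF_PSNR"]

#: Sentinel returned when MSE is exactly zero (identical volumes).
INF_PSNR = math.inf


@dataclasses.dataclass
class SSIMParams:
    """SSIM configuration: window size/weights and stabilising constants."""

    window: int = 11
    window_kind: str = "gaussian"   # {"gaussian", "uniform"}
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.data_range <= 0:
            raise ValueError("data_range must be positive")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1, k2 must be positive")
        if self.window_kind not in ("gaussian", "uniform"):
            raise ValueError(f"unknown window_kind {self.window_kind!r}")

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2


def _as_array(x) -> np.ndarray:
    if isinstance(x, ImageVolume):
        return x.voxels
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x)


def psnr(pred, ref, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the inputs are identical."""
    p, r = _as_array(pred), _as_array(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {r.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((p.astype(np.float64) - r.astype(np.float64)) ** 2))
    if mse == 0.0:
        return INF_PSNR
    return 10.0 * math.log10(data_range ** 2 / mse)


def _gaussian_kernel1d(window: int, sigma: float) -> np.ndarray:
    r = np.arange(window) - window // 2
    k = np.exp(-0.5 * (r / sigma) ** 2)
    return k / k.sum()


def gaussian_window2d(window: int, sigma: float) -> np.ndarray:
    k = _gaussian_kernel1d(window, sigma)
    w = np.outer(k, k)
    return (w / w.sum()).astype(np.float64)


def _ssim_from_moments(mu_a, mu_b, e_aa, e_bb, e_ab, c1, c2):
    va = e_aa - mu_a * mu_a
    vb = e_bb - mu_b * mu_b
    cov = e_ab - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a * mu_a + mu_b * mu_b + c1) * (va + vb + c2)
    return num / den


def ssim2d(a, b, params: SSIMParams | None = None) -> float:
    """Mean SSIM over valid sliding windows of a 2D frame pair."""
    params = params or SSIMParams()
    x, y = _as_array(a).astype(np.float64), _as_array(b).astype(np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if x.ndim != 2:
        raise ValueError(f"ssim2d expects 2D frames, got shape {x.shape}")
    w = params.window
    if min(x.shape) < w:
        raise ValueError(f"frame {x.shape} smaller than window {w}")
    if params.window_kind == "gaussian":
        kern = gaussian_window2d(w, params.sigma)

        def filt(z):
            from scipy.signal import fftconvolve
            return fftconvolve(z, kern, mode="valid")
    else:
        m = w // 2

        def filt(z):
            return uniform_filter(z, size=w, mode="nearest")[m:-m or None, m:-m or None]

    mu_a, mu_b = filt(x), filt(y)
    s = _ssim_from_moments(mu_a, mu_b, filt(x * x), filt(y * y), filt(x * y),
                           params.c1, params.c2)
    return float(s.mean())


def ssim3d(a, b, params: SSIMParams | None = None) -> float:
    """SSIM with a 3D sliding window over a volume pair.

    Defaults to a 7x7x7 uniform window; for stacks thinner than the window
    the depth extent clamps to n_frames (an even window keeps the uniform
    filter well-defined, the mean is then over the valid region).
    """
    params = params or SSIMParams(window=7, window_kind="uniform")
    x, y = _as_array(a).astype(np.float64), _as_array(b).astype(np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if x.ndim != 3:
        raise ValueError(f"ssim3d expects 3D volumes, got shape {x.shape}")
    w = params.window
    if x.shape[1] < w or x.shape[2] < w:
        raise ValueError(f"volume {x.shape} smaller than window {w} in a spatial axis")
    wz = min(w, x.shape[0])
    size = (wz, w, w)
    margins = tuple(s // 2 for s in size)

    def filt(z):
        f = uniform_filter(z, size=size, mode="nearest")
        sl = tuple(slice(m, d - (s - 1 - m)) for m, s, d in zip(margins, size, z.shape))
        return f[sl]

    s = _ssim_from_moments(filt(x), filt(y), filt(x * x), filt(y * y), filt(x * y),
                           params.c1, params.c2)
    return float(s.mean())


def ssim_loss(pred: Tensor, target: Tensor, params: SSIMParams | None = None) -> Tensor:
    """Differentiable loss ``1 − mean SSIM`` over (batch, frame) 2D frames.

    Accepts 5-axis [B, T, C, H, W] feature tensors (or any layout whose last
    two axes are spatial).  The Gaussian window is a fixed, non-trainable
    convolution kernel, so the loss is differentiable with respect to
    ``pred`` end to end.
    """
    params = params or SSIMParams()
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    h, w_ = pred.shape[-2], pred.shape[-1]
    w = params.window
    if h < w or w_ < w:
        raise ValueError(f"frames ({h}, {w_}) smaller than SSIM window {w}")
    n_maps = int(np.prod(pred.shape[:-2]))
    x = pred.reshape(n_maps, 1, h, w_)
    y = target if isinstance(target, Tensor) else Tensor(target)
    y = y.detach().reshape(n_maps, 1, h, w_)
    if params.window_kind == "gaussian":
        k1d = _gaussian_kernel1d(w, params.sigma)
    else:
        k1d = np.full(w, 1.0 / w)
    # separable window: (w,1) then (1,w) valid-mode convolutions
    kern_v = Tensor(k1d.reshape(1, 1, w, 1).astype(np.float32))
    kern_h = Tensor(k1d.reshape(1, 1, 1, w).astype(np.float32))

    def filt(z: Tensor) -> Tensor:
        return z.conv2d(kern_v, padding=0).conv2d(kern_h, padding=0)

    mu_a, mu_b = filt(x), filt(y)
    e_aa, e_bb, e_ab = filt(x * x), filt(y * y), filt(x * y)
    va = e_aa - mu_a * mu_a
    vb = e_bb - mu_b * mu_b
    cov = e_ab - mu_a * mu_b
    c1, c2 = params.c1, params.c2
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a * mu_a + mu_b * mu_b + c1) * (va + vb + c2)
    return 1.0 - (num / den).mean()
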