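"""Fused elementwise/normalisation kernels (numba; numpy fallback).

GELU and per-map instance normalisation touch every activation twice per
step; fusing their passes avoids a cascade of full-size numpy temporaries.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


@njit(cache=True, fastmath=True)
def _gelu_fwd_jit(x, y):
    for i in range(x.size):
        v = x.flat[i]
        y.flat[i] = 0.5 * v * (1.0 + math.erf(v * _INV_SQRT2))


@njit(cache=True, fastmath=True)
def _gelu_bwd_jit(x, g, dx):
    for i in range(x.size):
        v = x.flat[i]
        cdf = 0.5 * (1.0 + math.erf(v * _INV_SQRT2))
        pdf = math.exp(-0.5 * v * v) * _INV_SQRT2PI
        dx.flat[i] = g.flat[i] * (cdf + v * pdf)


@njit(cache=True, fastmath=True)
def _instnorm_fwd_jit(x2, y2, inv, eps):
    # x2, y2: [M, HW]; inv: [M] receives 1/std per map
    M, L = x2.shape
    for m in range(M):
        s = 0.0
        for i in range(L):
            s += x2[m, i]
        mu = s / L
        s2 = 0.0
        for i in range(L):
            d = x2[m, i] - mu
            s2 += d * d
        iv = 1.0 / math.sqrt(s2 / L + eps)
        inv[m] = iv
        for i in range(L):
            y2[m, i] = (x2[m, i] - mu) * iv


@njit(cache=True, fastmath=True)
def _instnorm_bwd_jit(y2, g2, inv, dx2):
    M, L = y2.shape
    for m in range(M):
        gs = 0.0
        gys = 0.0
        for i in range(L):
            gs += g2[m, i]
            gys += g2[m, i] * y2[m, i]
        gm = gs / L
        gym = gys / L
        iv = inv[m]
        for i in range(L):
            dx2[m, i] = iv * (g2[m, i] - gm - y2[m, i] * gym)


def gelu_forward(x: np.ndarray) -> np.ndarray:
    if _HAVE_NUMBA:
        y = np.empty_like(x)
        _gelu_fwd_jit(x, y)
        return y
    from scipy.special import erf
    return (0.5 * x * (1.0 + erf(x * _INV_SQRT2))).astype(x.dtype)


def gelu_backward(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    if _HAVE_NUMBA:
        dx = np.empty_like(x)
        _gelu_bwd_jit(x, g, dx)
        return dx
    from scipy.special import erf
    cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    pdf = np.exp(-0.5 * x * x) * _INV_SQRT2PI
    return (g * (cdf + x * pdf)).astype(x.dtype)


def instnorm_forward(x: np.ndarray, eps: float):
    """x [..., H, W] -> (y standardised per map, inv 1/std per map)."""
    lead = x.shape[:-2]
    M = int(np.prod(lead)) if lead else 1
    L = x.shape[-2] * x.shape[-1]
    x2 = np.ascontiguousarray(x).reshape(M, L)
    if _HAVE_NUMBA:
        y2 = np.empty_like(x2)
        inv = np.empty(M, dtype=x.dtype)
        _instnorm_fwd_jit(x2, y2, inv, eps)
        return y2.reshape(x.shape), inv
    mu = x2.mean(axis=1, keepdims=True)
    xc = x2 - mu
    var = np.mean(xc * xc, axis=1, keepdims=True)
    inv = (1.0 / np.sqrt(var + eps)).astype(x.dtype)
    return (xc * inv).reshape(x.shape), inv.ravel()


def instnorm_backward(y: np.ndarray, g: np.ndarray, inv: np.ndarray) -> np.ndarray:
    lead = y.shape[:-2]
    M = int(np.prod(lead)) if lead else 1
    L = y.shape[-2] * y.shape[-1]
    y2 = np.ascontiguousarray(y).reshape(M, L)
    g2 = np.ascontiguousarray(g).reshape(M, L)
    if _HAVE_NUMBA:
        dx2 = np.empty_like(y2)
        _instnorm_bwd_jit(y2, g2, inv, dx2)
        return dx2.reshape(y.shape)
    gm = g2.mean(axis=1, keepdims=True)
    gym = (g2 * y2).mean(axis=1, keepdims=True)
    return (inv[:, None] * (g2 - gm - y2 * gym)).reshape(y.shape).astype(y.dtype)
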