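"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the operations the CNNT
architecture and the SSIM training loss need: broadcasting arithmetic,
batched matmul, 2D convolution, nearest-neighbour upsampling, softmax,
GELU, reductions and shape manipulation.  Gradients are accumulated by
a topological sweep over the recorded graph, in the style of the classic
define-by-run frameworks.

All operations accept :class:`Tensor` or plain array-likes; plain inputs
are treated as constants.  Gradient correctness is covered by
finite-difference tests.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

from . import _conv, _fused

__all__ = ["Tensor", "concatenate", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the original operand shape."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind in "iub":
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph bookkeeping ---------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        # own=True: the caller guarantees `grad` is freshly allocated (or a
        # view of a buffer no longer read by anyone), so it can be stored
        # without a defensive copy.
        if self.grad is None:
            if own and grad.dtype == self.data.dtype:
                self.grad = grad
            else:
                self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
                # free the tape as we go; leaves keep their grads
                node._backward = None
                node._prev = ()

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data + b.data

        def backward():
            if a.requires_grad:
                ga = _sum_to_shape(out.grad, a.shape)
                a._accum(ga, own=ga is not out.grad)
            if b.requires_grad:
                gb = _sum_to_shape(out.grad, b.shape)
                b._accum(gb, own=gb is not out.grad)

        out = Tensor._make(out_data, (a, b), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward():
            if a.requires_grad:
                a._accum(-out.grad, own=True)

        out = Tensor._make(-a.data, (a,), backward)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data * b.data

        def backward():
            if a.requires_grad:
                a._accum(_sum_to_shape(out.grad * b.data, a.shape), own=True)
            if b.requires_grad:
                b._accum(_sum_to_shape(out.grad * a.data, b.shape), own=True)

        out = Tensor._make(out_data, (a, b), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data / b.data

        def backward():
            if a.requires_grad:
                a._accum(_sum_to_shape(out.grad / b.data, a.shape), own=True)
            if b.requires_grad:
                b._accum(_sum_to_shape(-out.grad * out_data / b.data, b.shape),
                         own=True)

        out = Tensor._make(out_data, (a, b), backward)
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def backward():
            if a.requires_grad:
                a._accum(out.grad * p * a.data ** (p - 1), own=True)

        out = Tensor._make(out_data, (a,), backward)
        return out

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward():
            if a.requires_grad:
                a._accum(out.grad * 0.5 / out_data, own=True)

        out = Tensor._make(out_data, (a,), backward)
        return out

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward():
            if a.requires_grad:
                a._accum(out.grad * out_data, own=True)

        out = Tensor._make(out_data, (a,), backward)
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if not a.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape))

        out = Tensor._make(out_data, (a,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        out_data = a.data.reshape(shape)

        def backward():
            if a.requires_grad:
                a._accum(out.grad.reshape(a.shape), own=True)

        out = Tensor._make(out_data, (a,), backward)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        out_data = a.data.transpose(axes)
        inv = np.argsort(axes)

        def backward():
            if a.requires_grad:
                a._accum(out.grad.transpose(inv), own=True)

        out = Tensor._make(out_data, (a,), backward)
        return out

    def swapaxes(self, ax1: int, ax2: int):
        axes = list(range(self.ndim))
        axes[ax1], axes[ax2] = axes[ax2], axes[ax1]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def backward():
            if a.requires_grad:
                g = np.zeros_like(a.data)
                np.add.at(g, idx, out.grad)
                a._accum(g, own=True)

        out = Tensor._make(out_data, (a,), backward)
        return out

    # -- matmul ---------------------------------------------------------
    def __matmul__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data @ b.data

        def backward():
            g = out.grad
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_sum_to_shape(ga, a.shape), own=True)
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_sum_to_shape(gb, b.shape), own=True)

        out = Tensor._make(out_data, (a, b), backward)
        return out

    # -- nonlinearities -------------------------------------------------
    def gelu(self):
        """Exact GELU: x * Phi(x) with the Gaussian CDF."""
        a = self
        x = a.data
        out_data = _fused.gelu_forward(x)

        def backward():
            if a.requires_grad:
                a._accum(_fused.gelu_backward(x, out.grad), own=True)

        out = Tensor._make(out_data, (a,), backward)
        return out

    def softmax(self, axis: int = -1):
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        e = np.exp(a.data - m)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward():
            if a.requires_grad:
                g = out.grad
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                a._accum(out_data * (g - dot), own=True)

        out = Tensor._make(out_data, (a,), backward)
        return out

    def instance_norm(self, eps: float = 1e-5):
        """Standardise each [..., H, W] map to zero mean, unit variance."""
        a = self
        y, inv = _fused.instnorm_forward(a.data, eps)

        def backward():
            if a.requires_grad:
                a._accum(_fused.instnorm_backward(y, out.grad, inv), own=True)

        out = Tensor._make(y, (a,), backward)
        return out

    # -- image ops ------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2D cross-correlation over [N, C, H, W] with weight [Co, C, kh, kw]."""
        a, w = self, weight
        N, C, H, W = a.shape
        Co, Ci, kh, kw = w.shape
        if Ci != C:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Ci}")
        s, p = stride, padding
        xp = np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else a.data
        Ho = (H + 2 * p - kh) // s + 1
        Wo = (W + 2 * p - kw) // s + 1
        wmat = np.ascontiguousarray(w.data.reshape(Co, -1))
        out_data = _conv.conv_forward(xp, wmat, kh, kw, s, Ho, Wo)
        if bias is not None:
            out_data += bias.data.reshape(1, Co, 1, 1)

        parents = (a, w) if bias is None else (a, w, bias)

        def backward():
            g = out.grad  # [N, Co, Ho, Wo]
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)), own=True)
            dw2d, dxp = _conv.conv_backward(
                xp, wmat, g, kh, kw, s, Ho, Wo,
                need_dw=w.requires_grad, need_dx=a.requires_grad)
            if dw2d is not None:
                w._accum(dw2d.reshape(w.shape), own=True)
            if dxp is not None:
                a._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp, own=True)

        out = Tensor._make(out_data, parents, backward)
        return out

    def upsample2x(self):
        """Nearest-neighbour 2x upsampling on the last two axes of [N, C, H, W]."""
        a = self
        out_data = a.data.repeat(2, axis=-2).repeat(2, axis=-1)

        def backward():
            if a.requires_grad:
                N, C, H, W = a.shape
                g = out.grad.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5))
                a._accum(g, own=True)

        out = Tensor._make(out_data, (a,), backward)
        return out


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [(_as_tensor(t)) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out_data.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)], own=True)

    out = Tensor._make(out_data, tuple(ts), backward)
    return out
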