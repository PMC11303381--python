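"""Layer primitives built on the autograd :class:`~cnnt.nn.tensor.Tensor`."""

from __future__ import annotations

import math
from collections import OrderedDict
from typing import Iterator

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Parameter", "Conv2d", "InstanceNorm2d", "Sequential"]


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        # Parameters are always leaves that require grad, even when created
        # inside a no_grad block (e.g. while loading a checkpoint).
        self.requires_grad = True


class Module:
    def __init__(self):
        self._parameters: OrderedDict[str, Parameter] = OrderedDict()
        self._modules: OrderedDict[str, Module] = OrderedDict()

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_parameters", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((n, p.data.copy()) for n, p in self.named_parameters())

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise KeyError(
                f"state dict mismatch (missing: {sorted(missing)}, "
                f"unexpected: {sorted(unexpected)})")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape}, "
                    f"model {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    """3x3 (or kxk) 2D convolution with He-style fan-in initialisation.

    ``zero_init=True`` zeroes weight and bias, used for residual output
    projections so freshly built blocks start as the identity.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size=3,
                 stride: int = 1, padding: int | None = None,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        self.stride = stride
        self.padding = kh // 2 if padding is None else padding
        if zero_init:
            w = np.zeros((out_channels, in_channels, kh, kw), dtype=np.float32)
        else:
            rng = rng if rng is not None else np.random.default_rng()
            fan_in = in_channels * kh * kw
            std = math.sqrt(2.0 / fan_in)
            w = rng.normal(0.0, std, (out_channels, in_channels, kh, kw)).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial axes.

    For the 5-axis feature tensors of the model the (batch, frame) axes are
    folded into the sample axis, so normalisation is per (sample, frame,
    channel) — each 2D feature map is standardised independently.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.eps = eps
        self.affine = affine
        if affine:
            self.gamma = Parameter(np.ones(num_channels, dtype=np.float32))
            self.beta = Parameter(np.zeros(num_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        y = x.instance_norm(self.eps)
        if self.affine:
            C = self.gamma.shape[0]
            y = y * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)
        return y


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
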