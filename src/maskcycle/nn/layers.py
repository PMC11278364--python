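"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class; collects parameters by walking attributes."""

    def parameters(self) -> Iterator[Tensor]:
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield item

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        arrays = list(arrays)
        params = list(self.parameters())
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float32).copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    """Strided 2-D convolution; weights drawn N(0, init_gain^2)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, pad_mode: str = "zero",
                 bias: bool = True, init_gain: float = 0.02):
        self.stride = stride
        self.padding = padding
        self.pad_mode = pad_mode
        self.weight = Tensor(
            rng.normal(0.0, init_gain, size=(out_ch, in_ch, kernel, kernel)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if self.padding and self.pad_mode == "reflect":
            x = ag.pad2d(x, self.padding, "reflect")
            return ag.conv2d(x, self.weight, self.bias, stride=self.stride)
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization without learned affine."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = ag.tmean(ag.mul(centered, centered), axis=(2, 3), keepdims=True)
        return ag.div(centered, ag.power(var + Tensor(np.float32(self.eps)), 0.5))


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return ag.leaky_relu(x, self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.tanh(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(x)


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.upsample_nearest2x(x)


class Sequential(Module):
    def __init__(self, *blocks: Module):
        self.blocks = list(blocks)

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x
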