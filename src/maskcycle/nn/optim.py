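"""Optimizers and the step learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Optimizer:
    def __init__(self, params):
        self.params: list[Tensor] = list(params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, params, lr: float = 2e-4, betas: tuple[float, float] = (0.5, 0.999),
                 eps: float = 1e-8):
        super().__init__(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class SGD(Optimizer):
    """SGD with momentum and decoupled-into-gradient weight decay.

    Matches the common deep-learning convention: g <- g + wd*w, then
    buf <- momentum*buf + g and w <- w - lr*buf.
    """

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.95,
                 weight_decay: float = 0.001):
        super().__init__(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, buf in zip(self.params, self.buf):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= self.lr * buf


def step_lr(base_lr: float, epoch: int, step_size: int, gamma: float) -> float:
    """Learning rate at a 0-based epoch: base_lr * gamma**floor(epoch/step_size)."""
    if step_size <= 0:
        return base_lr
    return base_lr * gamma ** (epoch // step_size)
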