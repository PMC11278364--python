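"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small engine sized for the convolutional models in this
package: a :class:`Tensor` wraps a float32 ndarray and records a backward
closure per operation.  Only the primitives the generators, discriminators
and the U-Net need are implemented (elementwise arithmetic, reductions,
activations, padding, channel concatenation, nearest-neighbour upsampling
and strided 2-D convolution).  Gradients are accumulated in ``Tensor.grad``
by :meth:`Tensor.backward` in reverse topological order.

Graph recording is skipped entirely when no input requires gradients or
inside a :func:`no_grad` block, so inference costs no extra memory.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block (inference/validation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # always copy: the same backward gradient array may be handed to
            # several parents, and accumulation below is in place
            self.grad = np.array(grad, dtype=np.float32)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph as we go
                if node is not self:
                    node.grad = None
                node._backward = None
                node._parents = ()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise ops -------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))
    return Tensor._result(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.data.shape))
    return Tensor._result(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))
    return Tensor._result(a.data * b.data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))
    return Tensor._result(a.data / b.data, (a, b), backward)


def power(a: Tensor, p: float) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (p * np.power(a.data, p - 1)))
    return Tensor._result(np.power(a.data, p), (a,), backward)


def absolute(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.sign(a.data))
    return Tensor._result(np.abs(a.data), (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)
    return Tensor._result(np.log(a.data), (a,), backward)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - out_data * out_data))
    return Tensor._result(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))
    return Tensor._result(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)
    return Tensor._result(a.data * mask, (a,), backward)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    factor = np.where(a.data > 0, np.float32(1.0), np.float32(slope))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * factor)
    return Tensor._result(a.data * factor, (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    inside = (a.data > lo) & (a.data < hi)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * inside)
    return Tensor._result(np.clip(a.data, lo, hi), (a,), backward)


# -- reductions ------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape))
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accumulate(np.broadcast_to(gg, a.data.shape))
    return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        count = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.data.shape[i] for i in ax]))
    s = tsum(a, axis, keepdims)
    return mul(s, Tensor(np.float32(1.0 / count)))


# -- shape ops -------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])
    return Tensor._result(np.concatenate([t.data for t in tensors], axis=axis),
                          tuple(tensors), backward)


def _scatter_axis(g: np.ndarray, idx: np.ndarray, size: int, axis: int) -> np.ndarray:
    gm = np.moveaxis(g, axis, 0)
    out = np.zeros((size,) + gm.shape[1:], dtype=g.dtype)
    np.add.at(out, idx, gm)
    return np.moveaxis(out, 0, axis)


def pad2d(a: Tensor, pad: int, mode: str = "zero") -> Tensor:
    """Pad the two trailing spatial axes of an NCHW tensor."""
    if pad == 0:
        return a
    N, C, H, W = a.data.shape
    if mode == "zero":
        data = np.pad(a.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))

        def backward(g):
            if a.requires_grad:
                a._accumulate(g[:, :, pad:pad + H, pad:pad + W])
        return Tensor._result(data, (a,), backward)
    if mode == "reflect":
        idx_h = np.pad(np.arange(H), pad, mode="reflect")
        idx_w = np.pad(np.arange(W), pad, mode="reflect")
        data = a.data[:, :, idx_h][:, :, :, idx_w]

        def backward(g):
            if a.requires_grad:
                gh = _scatter_axis(g, idx_w, W, 3)
                a._accumulate(_scatter_axis(gh, idx_h, H, 2))
        return Tensor._result(data, (a,), backward)
    raise ValueError(f"unknown pad mode {mode!r}")


def upsample_nearest2x(a: Tensor) -> Tensor:
    N, C, H, W = a.data.shape
    data = a.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))
    return Tensor._result(data, (a,), backward)


# -- convolution -----------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation over NCHW input with OIHW weights."""
    if padding:
        x = pad2d(x, padding, "zero")
    N, C, H, W = x.data.shape
    F, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    if H < kh or W < kw:
        raise ValueError("conv2d input smaller than kernel")
    s = stride
    win = sliding_window_view(x.data, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    Ho, Wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(F, C * kh * kw)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out = out.reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, F)
        if w.requires_grad:
            w._accumulate((gmat.T @ cols).reshape(F, C, kh, kw))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dx = np.zeros((N, C, H, W), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dx[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[..., i, j]
            x._accumulate(dx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(np.ascontiguousarray(out), parents, backward)
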