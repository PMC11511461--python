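"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations the segmentation network needs are provided:
elementwise arithmetic, matmul, reductions, activations, 2-D
convolution, batch norm, average pooling, pixel shuffle, channel
softmax and concatenation. Gradients for the convolution and pooling
ops are hand-written for speed (im2col / reshape tricks); everything
runs in float32.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Tuple

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents: Tuple["Tensor", ...] = (),
                 backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        track = _grad_enabled and (requires_grad or any(p.requires_grad for p in parents))
        self.requires_grad = track
        self._parents = parents if track else ()
        self._backward = backward if track else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _wrap(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _wrap(-1.0)))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        o = _wrap(other)
        return mul(self, power(o, -1.0))

    def __neg__(self):
        return mul(self, _wrap(-1.0))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes broadcast during the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- elementwise / linear algebra ---------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def power(a: Tensor, p: float) -> Tensor:
    out_data = a.data**p

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1))

    return Tensor(out_data, parents=(a,), backward=bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=bw)


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return Tensor(out_data, parents=(a,), backward=bw)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(a,), backward=bw)


def leaky_relu(a: Tensor, slope: float = 0.01) -> Tensor:
    out_data = np.where(a.data > 0, a.data, slope * a.data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * np.where(a.data > 0, 1.0, slope).astype(np.float32))

    return Tensor(out_data, parents=(a,), backward=bw)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if a.requires_grad:
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.shape).astype(np.float32))

    return Tensor(out_data, parents=(a,), backward=bw)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    count = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), _wrap(1.0 / float(count)))


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return Tensor(out_data, parents=(a,), backward=bw)


def concat(tensors, axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]

    def bw(g):
        offset = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + s)
                t._accumulate(g[tuple(sl)])
            offset += s

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


# -- spatial ops ---------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 2-D convolution.

    x: (N, Cin, H, W); w: (Cout, Cin, k, k); b: (Cout,).
    """
    n, cin, h, wd = x.shape
    cout, _, k, _ = w.shape
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, cin, k, k, h, wd), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + h, j : j + wd]
    cols2 = cols.reshape(n, cin * k * k, h * wd)
    w2 = w.data.reshape(cout, cin * k * k)
    out_data = (w2 @ cols2).reshape(n, cout, h, wd) + b.data.reshape(1, cout, 1, 1)

    def bw(g):
        g2 = g.reshape(n, cout, h * wd)
        if b.requires_grad:
            b._accumulate(g2.sum(axis=(0, 2)))
        if w.requires_grad:
            dw2 = np.einsum("nof,ncf->oc", g2, cols2, optimize=True)
            w._accumulate(dw2.reshape(w.shape))
        if x.requires_grad:
            dcols = (w2.T @ g2).reshape(n, cin, k, k, h, wd)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i : i + h, j : j + wd] += dcols[:, :, i, j]
            x._accumulate(dxp[:, :, pad : pad + h, pad : pad + wd])

    return Tensor(out_data, parents=(x, w, b), backward=bw)


def avg_pool2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    out_data = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def bw(g):
        if x.requires_grad:
            gg = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x._accumulate(gg)

    return Tensor(out_data, parents=(x,), backward=bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)"""
    n, c, h, w = x.shape
    out_data = x.data.mean(axis=(2, 3))

    def bw(g):
        if x.requires_grad:
            x._accumulate(
                np.broadcast_to(g[:, :, None, None] / (h * w), x.shape).astype(np.float32)
            )

    return Tensor(out_data, parents=(x,), backward=bw)


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """(N, C*r*r, H, W) -> (N, C, rH, rW); channel c*r*r + i*r + j goes to
    output offset (i, j) inside each r x r block."""
    n, crr, h, w = x.shape
    c = crr // (r * r)
    if c * r * r != crr:
        raise ValueError("channel count not divisible by r^2")
    out_data = (
        x.data.reshape(n, c, r, r, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, c, h * r, w * r)
    )

    def bw(g):
        if x.requires_grad:
            gg = (
                g.reshape(n, c, h, r, w, r)
                .transpose(0, 1, 3, 5, 2, 4)
                .reshape(n, crr, h, w)
            )
            x._accumulate(gg)

    return Tensor(out_data, parents=(x,), backward=bw)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 of an (N, C, H, W) tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=1, keepdims=True)

    def bw(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=1, keepdims=True)
            x._accumulate(s * (g - dot))

    return Tensor(s, parents=(x,), backward=bw)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization; updates running stats in place
    when training."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * invstd[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data[None, :, None, None] * invstd[None, :, None, None]
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                gsum = g.sum(axis=(0, 2, 3), keepdims=True)
                gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                x._accumulate(gi * (g - gsum / m - xhat * gxsum / m))
            else:
                x._accumulate(gi * g)

    return Tensor(out_data, parents=(x, gamma, beta), backward=bw)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (N, F); w: (F, O); b: (O,)."""
    return add(matmul(x, w), b)
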