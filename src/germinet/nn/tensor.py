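"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tensor engine: float32 ndarrays, a tape of parent
links, and vectorized backward rules for the handful of operations the
detector needs (dense/conv linear algebra, pooling, normalization,
softmax/attention and the elementwise zoo).  Gradients accumulate into
``Tensor.grad``; graph construction is disabled inside ``no_grad()``.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True
_FLOP_TALLY: dict | None = None


@contextlib.contextmanager
def flop_tally():
    """Collect floating-point-operation counts of conv/matmul ops run inside.

    Convolutions are charged ``2*H*W*(Cin*K^2 + 1)*Cout`` at their output
    resolution (the bias term is included by convention whether or not the
    conv carries one); matrix multiplies are charged 2x their
    multiply-accumulates.  Pooling, normalization and activations are free.
    """
    global _FLOP_TALLY
    prev = _FLOP_TALLY
    _FLOP_TALLY = {"conv": 0, "matmul": 0}
    try:
        yield _FLOP_TALLY
    finally:
        _FLOP_TALLY = prev


@contextlib.contextmanager
def no_grad():
    """Context manager that suspends graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- graph helper --------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- elementwise ---------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bwd)

    def abs(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), bwd)

    def sigmoid(self):
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bwd)

    def silu(self):
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (s + out_data * (1.0 - s)))

        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bwd)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            full = out_data if keepdims or axis is None else np.expand_dims(out_data, axis)
            gg = g if keepdims or axis is None else np.expand_dims(g, axis)
            mask = (self.data == full).astype(np.float32)
            mask /= np.maximum(mask.sum(axis=axis, keepdims=True), 1.0) if axis is not None else max(mask.sum(), 1.0)
            self._accumulate(mask * gg)

        return Tensor._make(out_data, (self,), bwd)

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, key):
        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        return Tensor._make(self.data[key], (self,), bwd)

    # -- matmul ----------------------------------------------------------
    def __matmul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out_data = np.matmul(self.data, other.data)
        if _FLOP_TALLY is not None:
            k = self.data.shape[-1]
            _FLOP_TALLY["matmul"] += 2 * out_data.size * k
        return Tensor._make(out_data, (self, other), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
    )


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, bwd)


def chunk(t: Tensor, n: int, axis: int) -> list[Tensor]:
    step = t.shape[axis] // n
    out = []
    for i in range(n):
        sl = [slice(None)] * t.ndim
        sl[axis] = slice(i * step, (i + 1) * step)
        out.append(t[tuple(sl)])
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if t.requires_grad:
            gy = g * y
            t._accumulate(gy - y * gy.sum(axis=axis, keepdims=True))

    return Tensor._make(y, (t,), bwd)


def pad2d(t: Tensor, pad: int, value: float = 0.0) -> Tensor:
    if pad == 0:
        return t
    out_data = np.pad(
        t.data,
        ((0, 0), (0, 0), (pad, pad), (pad, pad)),
        constant_values=value,
    )

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g[:, :, pad:-pad, pad:-pad])

    return Tensor._make(out_data, (t,), bwd)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(N,C,Hp,Wp) -> col (N*Ho*Wo, C*kh*kw) plus output spatial dims."""
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(col), ho, wo


def _col2im(dcol: np.ndarray, xp_shape, kh: int, kw: int, stride: int, ho: int, wo: int):
    n, c, hp, wp = xp_shape
    dxp = np.zeros(xp_shape, dtype=np.float32)
    d = dcol.reshape(n, ho, wo, c, kh, kw).transpose(4, 5, 0, 3, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[i, j]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW, OIHW weights, same semantics as the
    standard deep-learning convolution layer."""
    cout, cin, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    col, ho, wo = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(cout, -1)
    out_data = col @ wmat.T
    if b is not None:
        out_data += b.data
    n = x.shape[0]
    out_data = out_data.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    if _FLOP_TALLY is not None:
        _FLOP_TALLY["conv"] += 2 * n * ho * wo * (cin * kh * kw + 1) * cout
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gflat = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        if w.requires_grad:
            w._accumulate((gflat.T @ col).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gflat.sum(axis=0))
        if x.requires_grad:
            dcol = gflat @ wmat
            dxp = _col2im(dcol, xp.shape, kh, kw, stride, ho, wo)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor._make(out_data, parents, bwd)


def avg_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    out_data = win.mean(axis=(4, 5))
    n, c, ho, wo = out_data.shape
    scale = 1.0 / (kernel * kernel)

    def bwd(g):
        if not x.requires_grad:
            return
        dxp = np.zeros(xp.shape, dtype=np.float32)
        gs = g * scale
        for i in range(kernel):
            for j in range(kernel):
                dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += gs
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)

    return Tensor._make(np.ascontiguousarray(out_data), (x,), bwd)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    xp = (
        np.pad(
            x.data,
            ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
        if padding
        else x.data
    )
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        if not x.requires_grad:
            return
        dxp = np.zeros(xp.shape, dtype=np.float32)
        for p in range(kernel * kernel):
            i, j = divmod(p, kernel)
            mask = (idx == p) * g
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += mask
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)

    return Tensor._make(np.ascontiguousarray(out_data), (x,), bwd)


def upsample_nearest2d(x: Tensor, scale: int) -> Tensor:
    out_data = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def bwd(g):
        if x.requires_grad:
            n, c, h, w = x.shape
            gg = g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
            x._accumulate(gg)

    return Tensor._make(out_data, (x,), bwd)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization on NCHW; updates running stats in place."""
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
    out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = g * gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                s1 = gi.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gi * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (gi - s1 / m - xhat * s2 / m) * invstd[None, :, None, None]
            else:
                dx = gi * invstd[None, :, None, None]
            x._accumulate(dx)

    return Tensor._make(out_data, (x, gamma, beta), bwd)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mean = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * invstd
    out_data = xhat * gamma.data + beta.data

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).reshape(-1, x.shape[-1]).sum(axis=0))
        if beta.requires_grad:
            beta._accumulate(g.reshape(-1, x.shape[-1]).sum(axis=0))
        if x.requires_grad:
            gi = g * gamma.data
            d = x.shape[-1]
            s1 = gi.sum(axis=-1, keepdims=True)
            s2 = (gi * xhat).sum(axis=-1, keepdims=True)
            x._accumulate((gi - s1 / d - xhat * s2 / d) * invstd)

    return Tensor._make(out_data, (x, gamma, beta), bwd)


def bce_with_logits(logits: Tensor, targets: np.ndarray, weight: np.ndarray | None = None) -> Tensor:
    """Numerically stable binary cross-entropy on raw logits.

    ``targets`` may be soft (e.g. IoU-aware quality targets in [0,1]).
    Returns the elementwise-weighted sum.
    """
    z, t = logits.data, np.asarray(targets, dtype=np.float32)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if weight is not None:
        loss = loss * weight
    out = loss.sum()

    def bwd(g):
        if logits.requires_grad:
            dz = 1.0 / (1.0 + np.exp(-z)) - t
            if weight is not None:
                dz = dz * weight
            logits._accumulate(g * dz)

    return Tensor._make(out, (logits,), bwd)
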