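"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operation set needed by the mixture-density readouts
and the convolutional backbone: broadcasting arithmetic, the elementwise
transcendentals appearing in the von Mises / Gaussian log-densities
(exp, log, cos, tanh, softplus, atan2), reductions, stable log-sum-exp,
2-D convolution and max pooling. Every function in this module accepts
either a :class:`Tensor` or a plain ndarray; with plain ndarrays it falls
through to NumPy, so the same density code serves both training (gradients
required) and analysis (no gradients).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "is_tensor", "value", "constant",
    "exp", "log", "cos", "sin", "tanh", "sqrt", "softplus", "relu",
    "clip", "clip_straight_through", "where", "atan2", "logsumexp",
    "concatenate",
    "conv2d", "maxpool2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")
    __array_priority__ = 100  # ndarray + Tensor defers to Tensor.__radd__

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- structure -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- autograd ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))
        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = _wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))
        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)
        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __truediv__(self, other):
        other = _wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))
        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p: float):
        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1))
        return Tensor(self.data ** p, parents=(self,), backward=bw)

    def __matmul__(self, other):
        other = _wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))
        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            self._accumulate(g.reshape(self.shape))
        return Tensor(self.data.reshape(shape), parents=(self,), backward=bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))
        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    def __getitem__(self, idx):
        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accumulate(acc)
        return Tensor(self.data[idx], parents=(self,), backward=bw)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def value(x) -> np.ndarray:
    """The underlying ndarray, whether or not ``x`` is a Tensor."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def constant(x) -> Tensor:
    return Tensor(x)


def _elementwise(x, fwd, dfdx):
    if isinstance(x, Tensor):
        y = fwd(x.data)

        def bw(g):
            x._accumulate(g * dfdx(x.data, y))
        return Tensor(y, parents=(x,), backward=bw)
    return fwd(np.asarray(x, dtype=np.float64))


def exp(x):
    return _elementwise(x, np.exp, lambda d, y: y)


def log(x):
    return _elementwise(x, np.log, lambda d, y: 1.0 / d)


def cos(x):
    return _elementwise(x, np.cos, lambda d, y: -np.sin(d))


def sin(x):
    return _elementwise(x, np.sin, lambda d, y: np.cos(d))


def tanh(x):
    return _elementwise(x, np.tanh, lambda d, y: 1.0 - y**2)


def sqrt(x):
    return _elementwise(x, np.sqrt, lambda d, y: 0.5 / y)


def _softplus_fwd(d):
    # stable: log(1+e^d) = max(d,0) + log1p(exp(-|d|))
    return np.maximum(d, 0.0) + np.log1p(np.exp(-np.abs(d)))


def softplus(x):
    return _elementwise(x, _softplus_fwd,
                        lambda d, y: 1.0 / (1.0 + np.exp(-d)))


def relu(x):
    return _elementwise(x, lambda d: np.maximum(d, 0.0),
                        lambda d, y: (d > 0).astype(np.float64))


def clip(x, lo, hi):
    """Bounded rectifier; gradient is zero outside [lo, hi] (hard clamp)."""
    return _elementwise(x, lambda d: np.clip(d, lo, hi),
                        lambda d, y: ((d >= lo) & (d <= hi)).astype(np.float64))


def clip_straight_through(x, lo, hi):
    """Forward identical to :func:`clip`; backward passes gradients that
    point back into ``[lo, hi]``.

    A hard clamp has zero gradient outside the interval, so a pre-activation
    that falls below ``lo`` during an early large-loss phase can never
    recover (the analogue of a dying ReLU). This variant keeps the exact
    forward semantics but lets saturated units be pulled back inside, while
    still blocking gradients that would push them further out.
    """
    if not isinstance(x, Tensor):
        return np.clip(np.asarray(x, dtype=np.float64), lo, hi)
    d = x.data
    y = np.clip(d, lo, hi)

    def bw(g):
        inside = (d >= lo) & (d <= hi)
        rescue = ((d < lo) & (g < 0)) | ((d > hi) & (g > 0))
        x._accumulate(np.where(inside | rescue, g, 0.0))
    return Tensor(y, parents=(x,), backward=bw)


def where(cond, a, b):
    cond = value(cond).astype(bool)
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        a, b = _wrap(a), _wrap(b)

        def bw(g):
            a._accumulate(_unbroadcast(np.where(cond, g, 0.0), a.shape))
            b._accumulate(_unbroadcast(np.where(cond, 0.0, g), b.shape))
        return Tensor(np.where(cond, a.data, b.data), parents=(a, b), backward=bw)
    return np.where(cond, a, b)


def atan2(y, x):
    if isinstance(y, Tensor) or isinstance(x, Tensor):
        y, x = _wrap(y), _wrap(x)
        r2 = x.data**2 + y.data**2

        def bw(g):
            y._accumulate(_unbroadcast(g * x.data / r2, y.shape))
            x._accumulate(_unbroadcast(-g * y.data / r2, x.shape))
        return Tensor(np.arctan2(y.data, x.data), parents=(y, x), backward=bw)
    return np.arctan2(y, x)


def logsumexp(x, axis=-1, keepdims=False):
    """Numerically stable log-sum-exp; the max shift is treated as constant."""
    m = value(x).max(axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    if isinstance(x, Tensor):
        shifted = x - Tensor(m)
        out = log(exp(shifted).sum(axis=axis, keepdims=True)) + Tensor(m)
        return out if keepdims else out.reshape(
            tuple(s for i, s in enumerate(out.shape)
                  if i != (axis % out.ndim)))
    out = np.log(np.exp(x - m).sum(axis=axis, keepdims=True)) + m
    return out if keepdims else np.squeeze(out, axis=axis)


def concatenate(tensors, axis=0):
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])
    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bw)


# -- convolution / pooling ------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    n, c, h, w = x.shape
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]                      # (N,C,Ho,Wo,kh,kw)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return cols, ho, wo


def conv2d(x, weight, bias=None, stride=(1, 1), padding=(0, 0)):
    """2-D convolution (cross-correlation) for NCHW input.

    ``x``: (N,C,H,W); ``weight``: (F,C,kh,kw); ``bias``: (F,).
    """
    xt, wt = _wrap(x), _wrap(weight)
    sh, sw = stride
    ph, pw = padding
    xd = xt.data
    if ph or pw:
        xd = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    f, c, kh, kw = wt.shape
    cols, ho, wo = _im2col(xd, kh, kw, sh, sw)        # (N,HoWo,Ckhkw)
    wmat = wt.data.reshape(f, -1)
    out = cols @ wmat.T                               # (N,HoWo,F)
    n = xd.shape[0]
    out = out.transpose(0, 2, 1).reshape(n, f, ho, wo)
    bt = _wrap(bias) if bias is not None else None
    if bt is not None:
        out = out + bt.data.reshape(1, f, 1, 1)

    parents = (xt, wt) + ((bt,) if bt is not None else ())

    def bw(g):
        gmat = g.reshape(n, f, ho * wo).transpose(0, 2, 1)   # (N,HoWo,F)
        wt._accumulate(np.einsum("nif,nik->fk", gmat, cols).reshape(wt.shape))
        if bt is not None:
            bt._accumulate(g.sum(axis=(0, 2, 3)))
        gcols = gmat @ wmat                                  # (N,HoWo,Ckhkw)
        gx = np.zeros_like(xd)
        gwin = gcols.reshape(n, ho, wo, c, kh, kw)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += \
                    gwin[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if ph or pw:
            gx = gx[:, :, ph:gx.shape[2] - ph or None, pw:gx.shape[3] - pw or None]
        xt._accumulate(gx)

    return Tensor(out, parents=parents, backward=bw)


def maxpool2d(x, kernel=(2, 2)):
    """Non-overlapping max pooling; trailing remainder rows/cols are dropped."""
    xt = _wrap(x)
    kh, kw = kernel
    n, c, h, w = xt.shape
    ho, wo = h // kh, w // kw
    xd = xt.data[:, :, :ho * kh, :wo * kw]
    blocks = xd.reshape(n, c, ho, kh, wo, kw).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, ho, wo, kh * kw)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(xt.data)
        gx[:, :, :ho * kh, :wo * kw] = (
            gflat.reshape(n, c, ho, wo, kh, kw)
                 .transpose(0, 1, 2, 4, 3, 5)
                 .reshape(n, c, ho * kh, wo * kw))
        xt._accumulate(gx)

    return Tensor(out, parents=(xt,), backward=bw)
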