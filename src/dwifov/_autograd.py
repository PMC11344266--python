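"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the slice-imputation networks need:
2-D convolution (via im2col), pointwise nonlinearities, broadcasting
add/mul, channel concatenation and scalar reductions.  Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` over a
topologically sorted graph.  Everything is deterministic: no threading,
no stochastic kernels.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "add", "mul", "concat", "conv2d", "relu", "leaky_relu",
    "tanh", "sigmoid", "softplus", "log", "absolute", "mean", "Adam",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager: ops executed inside build no graph (forward only)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        if not _GRAD_ENABLED:
            _parents, _backward, requires_grad = (), None, False
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad += g

    def _set_backward(self, fn):
        if self._parents:       # no-op under no_grad (graph-free tensors)
            self._backward = fn

    def backward(self):
        """Backpropagate from a scalar and tear the graph down.

        Teardown breaks the node↔closure reference cycles so large
        intermediate buffers are freed immediately by refcounting; the
        graph is single-use, as in a standard training step.
        """
        if self.data.ndim != 0 and self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward()
        for t in topo:
            t._backward = None
            t._parents = ()

    # -- operator sugar ----------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _parents=(a, b))

    def _backward():
        g = out.grad
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._set_backward(_backward)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, _parents=(a, b))

    def _backward():
        g = out.grad
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._set_backward(_backward)
    return out


def concat(tensors, axis=1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def _backward():
        pieces = np.split(out.grad, np.cumsum(sizes)[:-1], axis=axis)
        for t, g in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(g)

    out._set_backward(_backward)
    return out


def _pointwise(a, fn, dfn):
    y = fn(a.data)
    out = Tensor(y, _parents=(a,))

    def _backward():
        if a.requires_grad:
            a._accumulate(out.grad * dfn(a.data, y))

    out._set_backward(_backward)
    return out


def relu(a):
    return _pointwise(a, lambda x: np.maximum(x, 0),
                      lambda x, y: (x > 0).astype(x.dtype))


def leaky_relu(a, slope=0.2):
    return _pointwise(a, lambda x: np.where(x > 0, x, slope * x),
                      lambda x, y: np.where(x > 0, 1.0, slope).astype(x.dtype))


def tanh(a):
    return _pointwise(a, np.tanh, lambda x, y: 1.0 - y * y)


def sigmoid(a):
    def fn(x):
        return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return _pointwise(a, fn, lambda x, y: y * (1.0 - y))


def softplus(a):
    """log(1 + exp(x)), numerically stable; d/dx = sigmoid(x)."""
    def dfn(x, y):
        return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return _pointwise(a, lambda x: np.logaddexp(0.0, x), dfn)


def log(a):
    return _pointwise(a, np.log, lambda x, y: 1.0 / x)


def absolute(a):
    return _pointwise(a, np.abs, lambda x, y: np.sign(x))


def mean(a) -> Tensor:
    out = Tensor(np.asarray(a.data.mean(), dtype=a.dtype), _parents=(a,))

    def _backward():
        if a.requires_grad:
            a._accumulate(np.full_like(a.data, out.grad / a.data.size))

    out._set_backward(_backward)
    return out


def _im2col(x, k, stride, pad):
    """(B,C,H,W) -> columns (C*k*k, B*Ho*Wo) plus (B, Ho, Wo)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    B, C, Ho, Wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(1, 4, 5, 0, 2, 3)) \
        .reshape(C * k * k, B * Ho * Wo)
    return cols, (B, Ho, Wo)


def _conv_raw(x, w, stride, pad):
    """Forward cross-correlation; returns (y, cols) for gradient reuse."""
    F, C, k, _ = w.shape
    cols, (B, Ho, Wo) = _im2col(x, k, stride, pad)
    y = (w.reshape(F, -1) @ cols).reshape(F, B, Ho, Wo).transpose(1, 0, 2, 3)
    return np.ascontiguousarray(y), cols


def _conv_input_grad(g, w, stride, pad, x_shape):
    """dL/dx of a conv: (dilated) convolution of dL/dy with the flipped,
    channel-transposed kernel."""
    B, F, Ho, Wo = g.shape
    C, k = w.shape[1], w.shape[2]
    if stride > 1:
        gd = np.zeros((B, F, (Ho - 1) * stride + 1, (Wo - 1) * stride + 1),
                      dtype=g.dtype)
        gd[:, :, ::stride, ::stride] = g
    else:
        gd = g
    w_flip = np.ascontiguousarray(
        w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))   # (C,F,k,k)
    full, _ = _conv_raw(gd, w_flip, 1, k - 1)
    H, W = x_shape[2], x_shape[3]
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=g.dtype)
    dxp[:, :, :full.shape[2], :full.shape[3]] = full
    return dxp[:, :, pad:pad + H, pad:pad + W]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernels."""
    F, C, k, _ = w.data.shape
    if x.data.shape[1] != C:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[1]}, "
            f"kernel expects {C}")
    y, cols = _conv_raw(x.data, w.data, stride, pad)
    B, _, Ho, Wo = y.shape
    if b is not None:
        y += b.data.reshape(1, F, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _parents=parents)

    def _backward():
        g = out.grad                       # (B,F,Ho,Wo)
        if w.requires_grad:
            gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)) \
                .reshape(F, B * Ho * Wo)
            w._accumulate((gmat @ cols.T).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accumulate(_conv_input_grad(g, w.data, stride, pad,
                                           x.data.shape))

    out._set_backward(_backward)
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x spatial upsampling of an NCHW tensor."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(y, _parents=(x,))

    def _backward():
        if x.requires_grad:
            g = out.grad
            B, C, H2, W2 = g.shape
            x._accumulate(
                g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    out._set_backward(_backward)
    return out


class Adam:
    """Adaptive-moment SGD (the pix2pix defaults: lr 2e-4, betas 0.5/0.999)."""

    def __init__(self, params, lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
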