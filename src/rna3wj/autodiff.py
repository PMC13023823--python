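"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for small graph neural networks: broadcasting
arithmetic, matmul, elementwise nonlinearities, reshape/concat/slice,
row gather and segment (scatter-add) sum, and reductions.  Gradients are
accumulated into ``.grad`` of every tensor marked ``requires_grad`` after
calling :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

import math

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    for _ in range(nd):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping ------------------------------------------------
    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents),
                     _parents=tuple(p for p in parents if p.requires_grad))
        if out.requires_grad:
            out._backward = backward
        return out

    def _acc(self, g):
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
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

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._acc(_unbroadcast(g, self.shape))
            other._acc(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._acc(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._acc(_unbroadcast(g * other.data, self.shape))
            other._acc(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._acc(_unbroadcast(g / other.data, self.shape))
            other._acc(_unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def bw(g):
            self._acc(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._acc(g @ other.data.T)
            other._acc(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # -- nonlinearities ---------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._acc(g * out_data)

        return self._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._acc(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._acc(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._acc(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            self._acc(g * factor)

        return self._make(self.data * factor, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._acc(g * 0.5 / out_data)

        return self._make(out_data, (self,), bw)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            self._acc(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._acc(full)

        return self._make(self.data[key], (self,), bw)

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._acc(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._acc(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._acc(piece)

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 _parents=tuple(t for t in tensors if t.requires_grad))
    if out.requires_grad:
        out._backward = bw
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """x[index] along axis 0 (rows may repeat)."""
    index = np.asarray(index, dtype=np.int64)

    def bw(g):
        full = np.zeros_like(x.data)
        np.add.at(full, index, g)
        x._acc(full)

    return x._make(x.data[index], (x,), bw)


def segment_sum(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets (scatter-add)."""
    segments = np.asarray(segments, dtype=np.int64)
    out_data = np.zeros((num_segments,) + x.shape[1:])
    np.add.at(out_data, segments, x.data)

    def bw(g):
        x._acc(g[segments])

    return x._make(out_data, (x,), bw)


def segment_softmax(scores: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of ``scores`` (rows) grouped by segment id.

    The per-segment max is subtracted as a constant for numerical
    stability; softmax is invariant to it, so the gradient is exact.
    """
    segments = np.asarray(segments, dtype=np.int64)
    m = np.full((num_segments,) + scores.shape[1:], -np.inf)
    np.maximum.at(m, segments, scores.data)
    shifted = scores - Tensor(m[segments])
    e = shifted.exp()
    denom = segment_sum(e, segments, num_segments)
    return e / gather_rows(denom, segments)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-row layer normalization with learned gain and bias."""
    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=1, keepdims=True)
    return xc / (var + eps).sqrt() * gain + bias


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    """Glorot/Xavier-uniform initialized parameter tensor."""
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class AdamW:
    """Adam with decoupled weight decay, plus a plateau LR scheduler hook."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimizer LR when the monitored loss has
    not improved for ``patience`` epochs."""

    def __init__(self, optimizer: AdamW, factor: float = 0.5, patience: int = 10,
                 min_lr: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad = 0

    def step(self, value: float):
        if value < self.best - 1e-12:
            self.best = value
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad = 0
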