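"""Neural building blocks used by the dual-resolution junction model.

All layers operate on :class:`~rna3wj.autodiff.Tensor` objects and keep
their parameters in a ``name -> Tensor`` dict so networks can be saved and
restored exactly.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import (Tensor, concat, gather_rows, glorot, segment_softmax,
                       segment_sum, zeros)


class Layer:
    def __init__(self):
        self._params = {}

    def add_param(self, name: str, t: Tensor) -> Tensor:
        self._params[name] = t
        return t

    def parameters(self) -> dict:
        return dict(self._params)


class Linear(Layer):
    def __init__(self, rng, in_dim: int, out_dim: int, bias: bool = True):
        super().__init__()
        self.W = self.add_param("W", glorot(rng, in_dim, out_dim))
        self.b = self.add_param("b", zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out


class LayerNorm(Layer):
    def __init__(self, dim: int):
        super().__init__()
        self.gain = self.add_param("gain", Tensor(np.ones(dim), requires_grad=True))
        self.bias = self.add_param("bias", zeros(dim))

    def __call__(self, x: Tensor, eps: float = 1e-5) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        return xc / (var + eps).sqrt() * self.gain + self.bias


def dropout(x: Tensor, p: float, rng, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def _mean_weights(dst: np.ndarray, n: int, heads: int) -> Tensor:
    """Degree-normalized aggregation weights, 1/indeg per incoming edge."""
    deg = np.bincount(dst, minlength=n).astype(float)
    w = 1.0 / np.maximum(deg[dst], 1.0)
    return Tensor(np.repeat(w[:, None], heads, axis=1))


class TransformerConv(Layer):
    """Multi-head attention message passing over a typed graph.

    For target node i: out_i = W_skip x_i + sum_j alpha_ij (W_v x_j + W_ev e_ij)
    with alpha from scaled dot-product attention between W_q x_i and
    W_k x_j + W_ek e_ij, softmax over the incoming edges of i.  With
    ``attention=False`` the weights become degree-normalized means
    (plain graph-convolution aggregation).
    """

    def __init__(self, rng, in_dim: int, out_dim: int, heads: int = 2,
                 edge_dim: int = 3, attention: bool = True):
        super().__init__()
        assert out_dim % heads == 0
        self.heads = heads
        self.head_dim = out_dim // heads
        self.out_dim = out_dim
        self.attention = attention
        self.Wq = self.add_param("Wq", glorot(rng, in_dim, out_dim))
        self.Wk = self.add_param("Wk", glorot(rng, in_dim, out_dim))
        self.Wv = self.add_param("Wv", glorot(rng, in_dim, out_dim))
        self.Wek = self.add_param("Wek", glorot(rng, edge_dim, out_dim))
        self.Wev = self.add_param("Wev", glorot(rng, edge_dim, out_dim))
        self.Wskip = self.add_param("Wskip", glorot(rng, in_dim, out_dim))
        self.b = self.add_param("b", zeros(out_dim))

    def __call__(self, x: Tensor, src: np.ndarray, dst: np.ndarray,
                 edge_attr: Tensor) -> Tensor:
        n = x.shape[0]
        skip = x @ self.Wskip + self.b
        if len(src) == 0:
            return skip
        H, D = self.heads, self.head_dim
        E = len(src)
        k = gather_rows(x @ self.Wk, src) + edge_attr @ self.Wek
        v = gather_rows(x @ self.Wv, src) + edge_attr @ self.Wev
        if self.attention:
            q = gather_rows(x @ self.Wq, dst)
            score = (q.reshape(E, H, D) * k.reshape(E, H, D)).sum(axis=2) \
                * (1.0 / math.sqrt(D))
            alpha = segment_softmax(score, dst, n)
        else:
            alpha = _mean_weights(dst, n, H)
        msg = v.reshape(E, H, D) * alpha.reshape(E, H, 1)
        agg = segment_sum(msg, dst, n).reshape(n, self.out_dim)
        return agg + skip


class GATConv(Layer):
    """Two-head graph attention (GATv2-style scoring) with edge features
    and implicit self-loops; with ``attention=False`` aggregation is a
    degree-normalized mean."""

    def __init__(self, rng, dim: int, heads: int = 2, edge_dim: int = None,
                 attention: bool = True, leaky_slope: float = 0.2):
        super().__init__()
        assert dim % heads == 0
        self.heads = heads
        self.head_dim = dim // heads
        self.dim = dim
        self.attention = attention
        self.slope = leaky_slope
        self.Ws = self.add_param("Ws", glorot(rng, dim, dim))
        self.Wt = self.add_param("Wt", glorot(rng, dim, dim))
        self.Wv = self.add_param("Wv", glorot(rng, dim, dim))
        self.edge_dim = dim if edge_dim is None else edge_dim
        self.We = self.add_param("We", glorot(rng, self.edge_dim, dim))
        self.a = self.add_param("a", glorot(rng, self.head_dim, 1,
                                            shape=(heads, self.head_dim)))
        self.b = self.add_param("b", zeros(dim))

    def __call__(self, x: Tensor, src: np.ndarray, dst: np.ndarray,
                 edge_attr: Tensor) -> Tensor:
        n = x.shape[0]
        H, D = self.heads, self.head_dim
        # add self-loops with zero edge features
        loop = np.arange(n, dtype=np.int64)
        src = np.concatenate([src, loop]) if len(src) else loop
        dst = np.concatenate([dst, loop]) if len(dst) else loop
        E = len(src)
        e_emb = concat([edge_attr, Tensor(np.zeros((n, self.edge_dim)))], axis=0) \
            if edge_attr.shape[0] else Tensor(np.zeros((n, self.edge_dim)))
        edge_term = e_emb @ self.We
        v = gather_rows(x @ self.Wv, src) + edge_term
        if self.attention:
            feat = gather_rows(x @ self.Ws, src) + gather_rows(x @ self.Wt, dst) \
                + edge_term
            score = (feat.leaky_relu(self.slope).reshape(E, H, D)
                     * self.a.reshape(1, H, D)).sum(axis=2)
            alpha = segment_softmax(score, dst, n)
        else:
            alpha = _mean_weights(dst, n, H)
        msg = v.reshape(E, H, D) * alpha.reshape(E, H, 1)
        return segment_sum(msg, dst, n).reshape(n, self.dim) + self.b
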