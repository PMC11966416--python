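"""Informer encoder/decoder with ProbSparse self-attention.

ProbSparse attention ranks queries by the sparsity score
M(q) = max_k(q.k/sqrt(d)) - mean_k(q.k/sqrt(d)) and gives only the top
u = ceil(c * ln L_q) queries a full softmax row; the remaining queries fall
back to the mean of V (encoder) or the cumulative mean of V (causal
decoder).  At u = L_q the result equals dense attention exactly.  The
sequence between the two encoder layers is distilled by a kernel-3 1-D
convolution, ELU, and stride-2 max pooling, halving its length.
"""

from __future__ import annotations

import warnings

import numpy as np

from .autograd import Tensor, cat
from .layers import (
    Dropout,
    LayerNorm,
    Linear,
    Module,
    conv1d_same,
    max_pool1d,
)


def sparsity_scores(scores: np.ndarray) -> np.ndarray:
    """M(q) = max over keys minus mean over keys of the scaled dot products."""
    return scores.max(axis=-1) - scores.mean(axis=-1)


def probsparse_attention(
    q: Tensor, k: Tensor, v: Tensor, u: int, causal: bool = False
) -> Tensor:
    """ProbSparse scaled-dot-product attention on (B, H, L, d) tensors."""
    B, H, Lq, d = q.shape
    Lk = k.shape[2]
    if u > Lq:
        warnings.warn(f"u={u} exceeds query length {Lq}; clamping")
        u = Lq
    u = max(int(u), 1)
    scale = 1.0 / np.sqrt(d)
    scores = (q @ k.swapaxes(-1, -2)) * scale  # (B, H, Lq, Lk)

    mask = None
    if causal:
        if Lq != Lk:
            raise ValueError("causal attention requires Lq == Lk")
        mask = np.triu(np.full((Lq, Lk), -1e30), k=1)
        scores = scores + Tensor(mask)

    # query selection is a discrete decision: computed on detached scores
    m = sparsity_scores(scores.data)  # (B, H, Lq)
    if u >= Lq:
        sel = np.ones((B, H, Lq, 1))
    else:
        order = np.argpartition(-m, u - 1, axis=-1)[..., :u]
        sel = np.zeros((B, H, Lq, 1))
        np.put_along_axis(sel[..., 0], order, 1.0, axis=-1)

    attn = scores.softmax(axis=-1) @ v  # (B, H, Lq, dv)

    if causal:
        denom = Tensor(1.0 / np.arange(1, Lq + 1)[None, None, :, None])
        fallback = v.cumsum(axis=2) * denom
    else:
        fallback = v.mean(axis=2, keepdims=True) + Tensor(np.zeros((B, H, Lq, 1)))

    sel_t = Tensor(sel)
    return attn * sel_t + fallback * (1.0 - sel_t)


class MultiHeadProbSparse(Module):
    def __init__(self, d_model: int, n_heads: int, sparse_factor: float,
                 dropout: float, rng: np.random.Generator):
        assert d_model % n_heads == 0
        self.h = n_heads
        self.dh = d_model // n_heads
        self.c = sparse_factor
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.drop = Dropout(dropout)

    def _split(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        return x.reshape(B, L, self.h, self.dh).transpose(0, 2, 1, 3)

    def __call__(self, q_in: Tensor, kv_in: Tensor, rng, training: bool,
                 causal: bool = False, dense: bool = False) -> Tensor:
        B, Lq, D = q_in.shape
        q = self._split(self.wq(q_in))
        k = self._split(self.wk(kv_in))
        v = self._split(self.wv(kv_in))
        u = Lq if dense else int(np.ceil(self.c * np.log(max(Lq, 2))))
        ctx = probsparse_attention(q, k, v, u=min(u, Lq), causal=causal)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, Lq, D)
        return self.drop(self.wo(ctx), rng, training)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.lin1 = Linear(d_model, d_ff, rng)
        self.lin2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class EncoderLayer(Module):
    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 sparse_factor: float, dropout: float, rng):
        self.attn = MultiHeadProbSparse(d_model, n_heads, sparse_factor, dropout, rng)
        self.ln1 = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, d_ff, rng)
        self.ln2 = LayerNorm(d_model)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng, training: bool) -> Tensor:
        x = self.ln1(x + self.attn(x, x, rng, training))
        return self.ln2(x + self.drop(self.ffn(x), rng, training))


class Distil(Module):
    """Kernel-3 conv -> ELU -> stride-2 max pool; halves the sequence."""

    def __init__(self, d_model: int, rng):
        self.lin = Linear(3 * d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return max_pool1d(conv1d_same(x, self.lin).elu())


def sinusoidal_encoding(length: int, d_model: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc  # (length, d_model)


class InformerEncoder(Module):
    """Input projection + positional/calendar encodings + 2 encoder layers
    with one distilling step in between."""

    def __init__(self, n_features: int, d_model: int, n_heads: int, d_ff: int,
                 n_layers: int, sparse_factor: float, dropout: float, rng):
        self.proj = Linear(n_features, d_model, rng)
        self.cal_proj = Linear(3, d_model, rng)
        self.layers = [
            EncoderLayer(d_model, n_heads, d_ff, sparse_factor, dropout, rng)
            for _ in range(n_layers)
        ]
        self.distils = [Distil(d_model, rng) for _ in range(n_layers - 1)]
        self.d_model = d_model

    def embed(self, window: Tensor, calendar: Tensor | None) -> Tensor:
        B, W, _ = window.shape
        x = self.proj(window) + Tensor(sinusoidal_encoding(W, self.d_model))
        if calendar is not None:
            x = x + self.cal_proj(calendar)
        return x

    def __call__(self, window: Tensor, calendar: Tensor | None,
                 rng, training: bool) -> tuple[Tensor, Tensor]:
        if window.shape[1] < 4:
            raise ValueError("window length must be >= 4 for distilling")
        emb = self.embed(window, calendar)
        x = emb
        for i, layer in enumerate(self.layers):
            x = layer(x, rng, training)
            if i < len(self.distils):
                x = self.distils[i](x)
        return x, emb


class InformerDecoder(Module):
    """Masked self-attention over a start-token segment plus one placeholder,
    cross-attention against the encoder output; returns the final position."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 sparse_factor: float, dropout: float, rng):
        self.self_attn = MultiHeadProbSparse(d_model, n_heads, sparse_factor,
                                             dropout, rng)
        self.cross_attn = MultiHeadProbSparse(d_model, n_heads, sparse_factor,
                                              dropout, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ln3 = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, d_ff, rng)
        self.drop = Dropout(dropout)

    def __call__(self, encoded: Tensor, start_token: Tensor,
                 rng, training: bool) -> Tensor:
        B, Ls, D = start_token.shape
        placeholder = Tensor(np.zeros((B, 1, D)))
        x = cat([start_token, placeholder], axis=1)
        x = self.ln1(x + self.self_attn(x, x, rng, training, causal=True))
        x = self.ln2(x + self.cross_attn(x, encoded, rng, training, dense=True))
        x = self.ln3(x + self.drop(self.ffn(x), rng, training))
        return x[:, -1, :]  # (B, d_model)
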