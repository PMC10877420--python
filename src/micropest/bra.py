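"""Bi-Level Routing Attention (BRA).

Sparse vision-transformer attention in two stages.  The feature map is
partitioned into an S x S grid of non-overlapping regions.  At the coarse
level each region is summarized by average-pooling its query/key tokens;
the region affinity matrix ``Ar = Qr @ Kr^T`` is pruned row-wise to the
top-k most affine regions, recorded in a routing index matrix ``Ir``.  At
the fine level every token in a query region attends (scaled dot-product
softmax attention) only to the tokens of its k routed regions, whose keys
and values are gathered into ``Kg``/``Vg``.  A local-context-enhancement
term — a depth-wise convolution over the value map — is added to the
attention output.

With k = S*S the gathered set is every token and BRA degenerates exactly
to dense global attention (plus LCE), which is the correctness oracle
used by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Conv2d, Linear, Module

__all__ = [
    "BRAConfig", "partition_tokens", "merge_tokens", "region_pool",
    "region_route", "gather_kv", "dense_attention_oracle",
    "BiLevelRoutingAttention",
]


@dataclass(frozen=True)
class BRAConfig:
    """Bi-level routing attention hyperparameters.

    S: regions per side (grid S x S); topk: routed regions kept per query
    region; heads: attention heads; lce_kernel: odd depth-wise kernel for
    local context enhancement; per_head_routing: compute the routing
    separately per head (cheaper shared routing if False).
    """

    S: int = 2
    topk: int = 4
    heads: int = 1
    lce_kernel: int = 5
    per_head_routing: bool = True

    def __post_init__(self):
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if not 1 <= self.topk <= self.S**2:
            raise ValueError(f"topk must lie in [1, S^2]={self.S**2}, got {self.topk}")
        if self.lce_kernel % 2 == 0:
            raise ValueError("lce_kernel must be odd")


def partition_tokens(x, S: int):
    """(N, C, H, W) -> (N, S^2, HW/S^2, C) region-major token layout."""
    n, c, h, w = x.shape
    if h % S or w % S:
        raise ValueError(f"feature map {h}x{w} not divisible into {S}x{S} regions")
    hr, wr = h // S, w // S
    t = x.reshape(n, c, S, hr, S, wr)
    t = t.transpose(0, 2, 4, 3, 5, 1)           # (N, S, S, hr, wr, C)
    return t.reshape(n, S * S, hr * wr, c)


def merge_tokens(t, S: int, h: int, w: int):
    """Inverse of :func:`partition_tokens`."""
    n = t.shape[0]
    c = t.shape[-1]
    hr, wr = h // S, w // S
    x = t.reshape(n, S, S, hr, wr, c)
    x = x.transpose(0, 5, 1, 3, 2, 4)
    return x.reshape(n, c, h, w)


def region_pool(tokens):
    """Per-region mean over the token axis: (..., S^2, n_tok, C) -> (..., S^2, C)."""
    return tokens.mean(axis=-2)


def region_route(qr: np.ndarray, kr: np.ndarray, k: int):
    """Coarse routing: affinity Ar = Qr Kr^T and its row-wise top-k index
    matrix Ir (ties broken toward the lower region index).

    qr, kr: (..., S^2, C) numpy arrays; returns (Ar, Ir) with Ir of shape
    (..., S^2, k).
    """
    s2 = qr.shape[-2]
    if k > s2:
        raise ValueError(f"k={k} exceeds the number of regions {s2}")
    ar = qr @ np.swapaxes(kr, -1, -2)
    order = np.argsort(-ar, axis=-1, kind="stable")  # stable => lower index wins ties
    return ar, order[..., :k]


def gather_kv(k_tok: np.ndarray, v_tok: np.ndarray, ir: np.ndarray):
    """Gather the token-level keys/values of each query region's routed
    regions: (..., S^2, n, C) + (..., S^2, k) -> (..., S^2, k*n, C)."""
    k_tok, v_tok, ir = np.asarray(k_tok), np.asarray(v_tok), np.asarray(ir)
    *batch, s2, n, c = k_tok.shape
    kk = k_tok.reshape(-1, s2, n, c)
    vv = v_tok.reshape(-1, s2, n, c)
    ii = ir.reshape(-1, s2, ir.shape[-1])
    kg = np.stack([kb[ib] for kb, ib in zip(kk, ii)])  # (B, S^2, k, n, C)
    vg = np.stack([vb[ib] for vb, ib in zip(vv, ii)])
    out_shape = (*batch, s2, ir.shape[-1] * n, c)
    return kg.reshape(out_shape), vg.reshape(out_shape)


def dense_attention_oracle(q: np.ndarray, k: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Reference dense softmax attention over flat token lists (..., T, d)."""
    d = q.shape[-1]
    logits = q @ np.swapaxes(k, -1, -2) / np.sqrt(d)
    logits = logits - logits.max(axis=-1, keepdims=True)
    w = np.exp(logits)
    w = w / w.sum(axis=-1, keepdims=True)
    return w @ v


def _one_hot(ir: np.ndarray, s2: int) -> np.ndarray:
    return np.eye(s2)[ir]  # (..., S^2, k, S^2)


class BiLevelRoutingAttention(Module):
    """BRA layer over an (N, C, H, W) feature map."""

    def __init__(self, channels: int, cfg: BRAConfig | None = None,
                 rng: np.random.Generator | None = None):
        cfg = cfg or BRAConfig()
        if channels % cfg.heads:
            raise ValueError(f"channels ({channels}) not divisible by heads ({cfg.heads})")
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.channels = channels
        self.wq = Linear(channels, channels, bias=False, rng=rng)
        self.wk = Linear(channels, channels, bias=False, rng=rng)
        self.wv = Linear(channels, channels, bias=False, rng=rng)
        self.lce = Conv2d(channels, channels, cfg.lce_kernel,
                          padding=cfg.lce_kernel // 2, groups=channels,
                          bias=False, rng=rng)

    def forward(self, x: Tensor, return_state: bool = False):
        cfg, c = self.cfg, self.channels
        n, _, h, w = x.shape
        s2 = cfg.S**2
        heads, d = cfg.heads, c // cfg.heads
        tokens = partition_tokens(x, cfg.S)          # (N, S^2, n_tok, C)
        n_tok = tokens.shape[2]
        q, k, v = self.wq(tokens), self.wk(tokens), self.wv(tokens)

        def split_heads(t):  # (N, S^2, n_tok, C) -> (N, heads, S^2, n_tok, d)
            return t.reshape(n, s2, n_tok, heads, d).transpose(0, 3, 1, 2, 4)

        qh, kh, vh = split_heads(q), split_heads(k), split_heads(v)
        # coarse level: routing on pooled (detached) region features
        qr = qh.data.mean(axis=-2)
        kr = kh.data.mean(axis=-2)
        if not cfg.per_head_routing:
            qr = np.broadcast_to(qr.mean(axis=1, keepdims=True), qr.shape)
            kr = np.broadcast_to(kr.mean(axis=1, keepdims=True), kr.shape)
        ar, ir = region_route(qr, kr, cfg.topk)      # (N, heads, S^2, S^2/k)
        # fine level: gather routed keys/values via one-hot matmul (differentiable)
        onehot = Tensor(_one_hot(ir, s2).reshape(n, heads, s2 * cfg.topk, s2))
        kg = (onehot @ kh.reshape(n, heads, s2, n_tok * d)) \
            .reshape(n, heads, s2, cfg.topk * n_tok, d)
        vg = (onehot @ vh.reshape(n, heads, s2, n_tok * d)) \
            .reshape(n, heads, s2, cfg.topk * n_tok, d)
        logits = (qh @ kg.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))
        attn = logits.softmax(axis=-1)
        o = attn @ vg                                # (N, heads, S^2, n_tok, d)
        o = o.transpose(0, 2, 3, 1, 4).reshape(n, s2, n_tok, c)
        out = merge_tokens(o, cfg.S, h, w)
        v_spatial = merge_tokens(v, cfg.S, h, w)
        out = out + self.lce(v_spatial)
        if return_state:
            return out, {"Ar": ar, "Ir": ir}
        return out
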