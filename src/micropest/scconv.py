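"""Spatial and Channel Reconstruction Convolution (SCConv).

Two units that suppress feature redundancy in a convolutional backbone:

* **SRU** (spatial reconstruction): group-normalizes the input, ranks
  channels by the magnitude of their learned GN scale gamma (channels a
  normalization keeps scaled up carry more spatial information), splits
  the feature map into an informative and a less-informative weighted
  stream, and cross-reconstructs the two streams (upper half of one added
  to the lower half of the other, then concatenated) so that information
  still flows between them.

* **CRU** (channel reconstruction): splits channels into an upper and a
  lower group, compresses both with 1x1 convolutions, transforms the
  upper group with a "rich" path (group-wise 3x3 conv + point-wise 1x1
  conv, summed) and the lower group with a cheap path (point-wise conv
  concatenated with the untouched compressed features), then fuses the
  two candidate maps with per-channel softmax weights beta1, beta2
  derived from global average pooling (beta1 + beta2 = 1).

The full block wraps SRU -> CRU between 1x1 channel compress/restore
convolutions and adds a residual connection, so its output shape always
equals its input shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Conv2d, GroupNorm, Module, concat

__all__ = ["SRUGate", "CRUState", "group_normalize", "SRU", "CRU", "SCConvBlock"]


@dataclass
class SRUGate:
    """Channel gate computed by the spatial reconstruction unit."""

    channel_weights: np.ndarray    # normalized |gamma|, sums to 1
    informative_mask: np.ndarray   # boolean per channel
    noninformative_mask: np.ndarray
    threshold: float

    def __post_init__(self):
        if np.any(self.informative_mask & self.noninformative_mask):
            raise ValueError("gate masks must partition the channel set")


@dataclass
class CRUState:
    """Fusion diagnostics of the channel reconstruction unit."""

    pooled: np.ndarray  # (N, 2, C) per-branch global-average-pooled scores
    beta1: np.ndarray   # (N, C)
    beta2: np.ndarray   # (N, C)


def group_normalize(x, num_groups: int, gamma=None, beta=None, eps: float = 1e-5):
    """Functional group normalization on an (N, C, H, W) array or tensor.

    Returns the same type as its input.  gamma/beta default to 1/0.
    """
    as_tensor = isinstance(x, Tensor)
    t = x if as_tensor else Tensor(np.asarray(x, dtype=float))
    c = t.shape[1]
    gn = GroupNorm(num_groups, c, eps=eps)
    if gamma is not None:
        gn.gamma.data[:] = np.asarray(gamma, dtype=float)
    if beta is not None:
        gn.beta.data[:] = np.asarray(beta, dtype=float)
    out = gn(t)
    return out if as_tensor else out.data


def _cross_reconstruct(x1: Tensor, x2: Tensor) -> Tensor:
    """Split both weighted streams channel-wise in half, cross-add, concat."""
    c = x1.shape[1]
    if c % 2:
        raise ValueError(f"cross-reconstruction requires an even channel count, got {c}")
    h = c // 2
    upper = x1[:, :h] + x2[:, h:]
    lower = x1[:, h:] + x2[:, :h]
    return concat([upper, lower], axis=1)


class SRU(Module):
    """Spatial reconstruction unit: separate by GN-gamma gate, cross-reconstruct.

    A channel is informative when its normalized weight W_c = |gamma_c| /
    sum|gamma| is at least ``threshold`` times the mean level 1/C; with the
    default threshold 1.0 the gate keeps channels whose gamma magnitude is
    above average.  The weighted streams W1*X and W2*X together carry
    exactly the mass of W*X, so reconstruction is an additive
    rearrangement.
    """

    def __init__(self, channels: int, *, gn_groups: int = 4, threshold: float = 1.0,
                 eps: float = 1e-5):
        self.gn = GroupNorm(gn_groups, channels, eps=eps)
        self.threshold = float(threshold)
        self.channels = channels

    def gate(self) -> SRUGate:
        gamma = np.abs(self.gn.gamma.data)
        total = gamma.sum()
        w = gamma / total if total > 0 else np.full_like(gamma, 1.0 / gamma.size)
        info = w >= self.threshold / gamma.size
        return SRUGate(w, info, ~info, self.threshold)

    def forward(self, x: Tensor, return_gate: bool = False):
        xn = self.gn(x)
        gate = self.gate()
        c = self.channels
        # differentiable normalized weights; masks are the (detached) gate
        w = self.gn.gamma.abs()
        w = w / w.sum()
        w1 = w * Tensor(gate.informative_mask.astype(float))
        w2 = w * Tensor(gate.noninformative_mask.astype(float))
        x1 = xn * w1.reshape(1, c, 1, 1)
        x2 = xn * w2.reshape(1, c, 1, 1)
        out = _cross_reconstruct(x1, x2)
        return (out, gate) if return_gate else out


class CRU(Module):
    """Channel reconstruction unit: split -> transform -> softmax fuse.

    split_ratio routes that fraction of channels to the rich upper path;
    squeeze_ratio compresses both splits before transformation.  The two
    candidate maps Y1 and Y2 both span all C output channels and are fused
    per channel as Y = beta1*Y1 + beta2*Y2.
    """

    def __init__(self, channels: int, *, split_ratio: float = 0.5,
                 squeeze_ratio: int = 2, gwc_groups: int = 2, gwc_kernel: int = 3,
                 rng: np.random.Generator | None = None):
        if not 0.0 < split_ratio < 1.0:
            raise ValueError("split_ratio must lie strictly between 0 and 1")
        if squeeze_ratio < 1:
            raise ValueError("squeeze_ratio must be >= 1")
        rng = rng or np.random.default_rng()
        c_up = int(round(channels * split_ratio))
        c_low = channels - c_up
        if c_up < 1 or c_low < 1:
            raise ValueError(f"split_ratio {split_ratio} leaves an empty branch for C={channels}")
        up_sq = max(1, c_up // squeeze_ratio)
        low_sq = max(1, c_low // squeeze_ratio)
        if low_sq >= channels:
            raise ValueError("squeeze plan leaves no room for the cheap-path concat")
        if up_sq % gwc_groups:
            raise ValueError(
                f"squeezed upper channels ({up_sq}) not divisible by gwc_groups ({gwc_groups})")
        self.c_up, self.c_low = c_up, c_low
        self.squeeze_up = Conv2d(c_up, up_sq, 1, bias=False, rng=rng)
        self.squeeze_low = Conv2d(c_low, low_sq, 1, bias=False, rng=rng)
        self.gwc = Conv2d(up_sq, channels, gwc_kernel, padding=gwc_kernel // 2,
                          groups=gwc_groups, bias=False, rng=rng)       # M_G
        self.pwc1 = Conv2d(up_sq, channels, 1, bias=False, rng=rng)     # M_P1
        self.pwc2 = Conv2d(low_sq, channels - low_sq, 1, bias=False, rng=rng)  # M_P2
        self.channels = channels

    def forward(self, x: Tensor, return_state: bool = False):
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        x_up = self.squeeze_up(x[:, : self.c_up])
        x_low = self.squeeze_low(x[:, self.c_up:])
        y1 = self.gwc(x_up) + self.pwc1(x_up)
        y2 = concat([self.pwc2(x_low), x_low], axis=1)
        s1 = y1.mean(axis=(2, 3))  # (N, C) global average pool
        s2 = y2.mean(axis=(2, 3))
        # per-channel softmax across the two branches
        m = np.maximum(s1.data, s2.data)
        e1 = (s1 - Tensor(m)).exp()
        e2 = (s2 - Tensor(m)).exp()
        z = e1 + e2
        b1, b2 = e1 / z, e2 / z
        n, c = b1.shape
        y = y1 * b1.reshape(n, c, 1, 1) + y2 * b2.reshape(n, c, 1, 1)
        if not return_state:
            return y
        state = CRUState(np.stack([s1.data, s2.data], axis=1), b1.data.copy(), b2.data.copy())
        return y, state


class SCConvBlock(Module):
    """1x1 compress -> SRU -> CRU -> 1x1 restore, with a residual skip."""

    def __init__(self, channels: int, *, compress_ratio: int = 2, gn_groups: int = 4,
                 gate_threshold: float = 1.0, split_ratio: float = 0.5,
                 squeeze_ratio: int = 2, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        mid = channels // compress_ratio
        if mid < 2 or mid % 2:
            raise ValueError(f"compressed channel count must be even and >= 2, got {mid}")
        if mid % gn_groups:
            gn_groups = 1
        self.compress = Conv2d(channels, mid, 1, bias=False, rng=rng)
        self.sru = SRU(mid, gn_groups=gn_groups, threshold=gate_threshold)
        up_sq = max(1, int(round(mid * split_ratio)) // squeeze_ratio)
        gwc_groups = 2 if up_sq % 2 == 0 else 1
        self.cru = CRU(mid, split_ratio=split_ratio, squeeze_ratio=squeeze_ratio,
                       gwc_groups=gwc_groups, rng=rng)
        self.restore = Conv2d(mid, channels, 1, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        z = self.compress(x)
        z = self.sru(z)
        z = self.cru(z)
        return x + self.restore(z)
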