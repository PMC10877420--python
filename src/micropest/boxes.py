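"""Bounding-box geometry and the IoU loss family.

Boxes are axis-aligned rectangles in continuous, 0-based pixel corner
coordinates (x1, y1, x2, y2) with x1 <= x2 and y1 <= y2.  Three regression
objectives are provided:

* plain IoU — overlap area over union area;
* CIoU loss — ``1 - IoU + rho^2/c^2 + alpha*v``, adding the normalized
  squared center distance (enclosure diagonal ``c``) and an aspect-ratio
  penalty ``v`` with balance factor ``alpha = v / (1 - IoU + v)``;
* MPDIoU — ``IoU - d1^2/(w^2+h^2) - d2^2/(w^2+h^2)``, where ``d1`` and
  ``d2`` are the distances between the two boxes' top-left and
  bottom-right corners and ``(w, h)`` are the *image* dimensions, so each
  penalty term lies in [0, 1].  Its loss is ``1 - MPDIoU``.

MPDIoU penalizes center offset and width/height deviation jointly through
the two corner distances, which makes the loss cheaper to evaluate than
CIoU and keeps a useful gradient for non-overlapping boxes.

Scalar functions operate on :class:`Box`; the ``*_t`` variants operate on
``(M, 4)`` autodiff tensors and are what the detector trains through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor

__all__ = [
    "Box", "ImageDims", "LossBreakdown",
    "iou", "ciou_loss", "mpdiou", "mpdiou_loss",
    "iou_t", "ciou_loss_t", "mpdiou_loss_t",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle, corner format, 0-based continuous pixels."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValueError(f"invalid box: corners not ordered ({self})")

    @property
    def w(self) -> float:
        return self.x2 - self.x1

    @property
    def h(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=float)


@dataclass(frozen=True)
class ImageDims:
    """Image width/height in pixels; the MPDIoU normalizer."""

    w: int
    h: int

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"image dimensions must be positive, got {self.w}x{self.h}")


@dataclass
class LossBreakdown:
    """Intermediate quantities of the loss computations (diagnostics)."""

    iou: float = 0.0
    rho2: float = 0.0   # squared center distance
    c2: float = 0.0     # squared enclosure diagonal
    v: float = 0.0      # aspect-ratio penalty
    alpha: float = 0.0  # aspect-ratio balance factor
    d1_sq: float = 0.0  # squared top-left corner distance
    d2_sq: float = 0.0  # squared bottom-right corner distance
    loss: float = 0.0


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes.

    Zero-area conventions: if the union has zero area the IoU is 0, except
    when both boxes degenerate to the *same* point, which counts as a
    perfect match (IoU 1).
    """
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    inter = max(ix, 0.0) * max(iy, 0.0)
    union = a.area + b.area - inter
    if union <= 0.0:
        return 1.0 if (a.area == 0.0 and a == b) else 0.0
    return inter / union


def ciou_loss(pred: Box, gt: Box) -> tuple[float, LossBreakdown]:
    """CIoU regression loss: 1 - IoU + rho^2/c^2 + alpha*v.

    gt must have positive width and height.  When both boxes collapse to
    the same point the center/enclosure term is defined as 0.
    """
    if gt.w <= 0 or gt.h <= 0:
        raise ValueError("ground-truth box must have positive width and height")
    bd = LossBreakdown(iou=iou(pred, gt))
    (cxa, cya), (cxb, cyb) = pred.center, gt.center
    bd.rho2 = (cxa - cxb) ** 2 + (cya - cyb) ** 2
    cw = max(pred.x2, gt.x2) - min(pred.x1, gt.x1)
    ch = max(pred.y2, gt.y2) - min(pred.y1, gt.y1)
    bd.c2 = cw**2 + ch**2
    center_term = bd.rho2 / bd.c2 if bd.c2 > 0 else 0.0
    if pred.w > 0 and pred.h > 0:
        bd.v = (4.0 / np.pi**2) * (np.arctan(gt.w / gt.h) - np.arctan(pred.w / pred.h)) ** 2
    else:
        bd.v = (4.0 / np.pi**2) * np.arctan(gt.w / gt.h) ** 2
    denom = 1.0 - bd.iou + bd.v
    bd.alpha = bd.v / denom if denom > 0 else 0.0
    bd.loss = 1.0 - bd.iou + center_term + bd.alpha * bd.v
    return bd.loss, bd


def mpdiou(a: Box, b: Box, img: ImageDims) -> tuple[float, LossBreakdown]:
    """Minimum-point-distance IoU: IoU minus image-normalized squared
    distances between matching top-left and bottom-right corners.

    The score lies in (-2, 1] and equals plain IoU exactly when the
    corners coincide.
    """
    bd = LossBreakdown(iou=iou(a, b))
    bd.d1_sq = (b.x1 - a.x1) ** 2 + (b.y1 - a.y1) ** 2
    bd.d2_sq = (b.x2 - a.x2) ** 2 + (b.y2 - a.y2) ** 2
    norm = float(img.w) ** 2 + float(img.h) ** 2
    score = bd.iou - bd.d1_sq / norm - bd.d2_sq / norm
    bd.loss = 1.0 - score
    return score, bd


def mpdiou_loss(a: Box, b: Box, img: ImageDims) -> float:
    """1 - MPDIoU; zero exactly when the boxes coincide."""
    score, _ = mpdiou(a, b, img)
    return 1.0 - score


# ---------------------------------------------------------------------------
# batched, differentiable variants (training path)
# ---------------------------------------------------------------------------

_EPS = 1e-9


def _corners(t: Tensor):
    return t[:, 0], t[:, 1], t[:, 2], t[:, 3]


def iou_t(pred: Tensor, gt: Tensor) -> Tensor:
    """Pairwise IoU of (M,4) corner-format tensors, differentiable."""
    ax1, ay1, ax2, ay2 = _corners(pred)
    bx1, by1, bx2, by2 = _corners(gt)
    iw = ax2.minimum(bx2) - ax1.maximum(bx1)
    ih = ay2.minimum(by2) - ay1.maximum(by1)
    inter = iw.maximum(0.0) * ih.maximum(0.0)
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / (union + _EPS)


def ciou_loss_t(pred: Tensor, gt: Tensor) -> Tensor:
    """Per-pair CIoU loss, (M,) tensor.  alpha is treated as a constant
    during gradient computation (standard convention)."""
    ax1, ay1, ax2, ay2 = _corners(pred)
    bx1, by1, bx2, by2 = _corners(gt)
    i = iou_t(pred, gt)
    rho2 = ((ax1 + ax2 - bx1 - bx2) ** 2 + (ay1 + ay2 - by1 - by2) ** 2) * 0.25
    cw = ax2.maximum(bx2) - ax1.minimum(bx1)
    ch = ay2.maximum(by2) - ay1.minimum(by1)
    c2 = cw**2 + ch**2 + _EPS
    wa, ha = ax2 - ax1, ay2 - ay1
    wb, hb = bx2 - bx1, by2 - by1
    v = ((wb / (hb + _EPS)).atan() - (wa / (ha + _EPS)).atan()) ** 2 * (4.0 / np.pi**2)
    alpha = Tensor(v.data / (1.0 - i.data + v.data + _EPS))  # no grad through alpha
    return 1.0 - i + rho2 / c2 + alpha * v


def mpdiou_loss_t(pred: Tensor, gt: Tensor, img: ImageDims) -> Tensor:
    """Per-pair MPDIoU loss (1 - MPDIoU), (M,) tensor."""
    ax1, ay1, ax2, ay2 = _corners(pred)
    bx1, by1, bx2, by2 = _corners(gt)
    norm = float(img.w) ** 2 + float(img.h) ** 2
    d1 = (bx1 - ax1) ** 2 + (by1 - ay1) ** 2
    d2 = (bx2 - ax2) ** 2 + (by2 - ay2) ** 2
    return 1.0 - (iou_t(pred, gt) - d1 * (1.0 / norm) - d2 * (1.0 / norm))
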