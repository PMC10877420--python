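"""Detection evaluation: greedy IoU matching, precision/recall/F1, AP, mAP.

Definitions follow the standard detection bookkeeping:

    Precision = TP / (TP + FP)          Recall = TP / (TP + FN)
    F1 = 2 P R / (P + R)                AP = area under the PR envelope
    mAP = mean of per-class APs

Matching is class-aware and greedy: detections are visited in descending
confidence, each consuming its best-IoU unmatched ground truth of the same
class when that IoU reaches the threshold (default 0.5); everything else
is a false positive, and unconsumed ground truths are false negatives.
AP uses all-points interpolation (the exact integral of the precision
envelope over recall) by default; the 11-point variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import Box, iou

__all__ = [
    "Detection", "GroundTruthBox", "EvalResult",
    "match_detections", "precision_recall_f1", "average_precision",
    "mean_ap", "evaluate",
]


@dataclass(frozen=True)
class Detection:
    box: Box
    class_id: str
    confidence: float

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0,1], got {self.confidence}")


@dataclass(frozen=True)
class GroundTruthBox:
    box: Box
    class_id: str


@dataclass
class EvalResult:
    tp: dict = field(default_factory=dict)
    fp: dict = field(default_factory=dict)
    fn: dict = field(default_factory=dict)
    precision: dict = field(default_factory=dict)
    recall: dict = field(default_factory=dict)
    f1: dict = field(default_factory=dict)
    pr_curve: dict = field(default_factory=dict)   # class -> list[(recall, precision)]
    ap_per_class: dict = field(default_factory=dict)
    map_value: float = 0.0

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: {
                    "tp": self.tp[c], "fp": self.fp[c], "fn": self.fn[c],
                    "precision": self.precision[c], "recall": self.recall[c],
                    "f1": self.f1[c], "ap": self.ap_per_class.get(c),
                }
                for c in sorted(self.tp)
            },
            "mAP": self.map_value,
        }


def match_detections(dets: list[Detection], gts: list[GroundTruthBox],
                     iou_threshold: float = 0.5):
    """Greedy confidence-ordered matching within one image.

    Returns (flags, fn_count): flags[i] is True when the i-th detection of
    the *confidence-sorted* order is a true positive, and the sorted
    detections themselves, as (sorted_dets, flags, fn_count).
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    sorted_dets = [dets[i] for i in order]
    consumed = [False] * len(gts)
    flags: list[bool] = []
    for det in sorted_dets:
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if consumed[j] or gt.class_id != det.class_id:
                continue
            ov = iou(det.box, gt.box)
            if ov > best_iou:
                best_iou, best_j = ov, j
        if best_j >= 0 and best_iou >= iou_threshold:
            consumed[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    fn = consumed.count(False)
    return sorted_dets, flags, fn


def precision_recall_f1(tp: int, fp: int, fn: int):
    """P, R and F1 from raw counts with zero-denominator conventions
    (each ratio is 0 when its denominator is 0)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _pr_points(flags: np.ndarray, n_gt: int):
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    return recall, precision


def average_precision(flags, confidences, n_gt: int, *,
                      interpolation: str = "all_points",
                      return_curve: bool = False):
    """AP of one class from per-detection TP flags and confidences.

    The PR curve is built over descending-confidence prefixes; AP is the
    area under the precision envelope over recall ("all_points") or the
    mean of the envelope at the 11 evenly spaced recall levels
    ("11_point").  n_gt must be >= 1; a class without ground truth has no
    defined AP.
    """
    if n_gt < 1:
        raise ValueError("AP is undefined for a class with no ground truth")
    flags = np.asarray(flags, dtype=bool)
    confidences = np.asarray(confidences, dtype=float)
    order = np.argsort(-confidences, kind="stable")
    flags = flags[order]
    if flags.size == 0:
        return (0.0, []) if return_curve else 0.0
    recall, precision = _pr_points(flags, n_gt)
    # precision envelope: running max from the right over [0 .. recall .. 1]
    r = np.concatenate(([0.0], recall, [1.0]))
    p = np.concatenate(([1.0], precision, [0.0]))
    env = np.maximum.accumulate(p[::-1])[::-1]
    if interpolation == "all_points":
        ap = float(np.sum((r[1:] - r[:-1]) * env[1:]))
    elif interpolation == "11_point":
        # envelope value at the smallest recall >= each of the 11 levels
        levels = np.linspace(0.0, 1.0, 11)
        vals = []
        for lv in levels:
            mask = r >= lv
            vals.append(float(env[mask].max()) if mask.any() else 0.0)
        ap = float(np.mean(vals))
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if return_curve:
        return ap, list(zip(recall.tolist(), precision.tolist()))
    return ap


def mean_ap(ap_per_class: dict) -> float:
    """Arithmetic mean of per-class APs over the evaluated classes."""
    if not ap_per_class:
        raise ValueError("mean AP requires at least one class with a defined AP")
    return float(np.mean(list(ap_per_class.values())))


def evaluate(detections_per_image: list[list[Detection]],
             gts_per_image: list[list[GroundTruthBox]],
             iou_threshold: float = 0.5,
             interpolation: str = "all_points") -> EvalResult:
    """Full evaluation over a dataset of images.

    Counts TP/FP/FN per class at the given IoU threshold, builds per-class
    PR curves and APs, and averages into mAP.  Classes that appear only in
    detections (no ground truth anywhere) are excluded from mAP.
    """
    if len(detections_per_image) != len(gts_per_image):
        raise ValueError("detections and ground truths must align per image")
    classes = sorted(
        {g.class_id for gts in gts_per_image for g in gts}
        | {d.class_id for dets in detections_per_image for d in dets}
    )
    res = EvalResult()
    per_class_flags = {c: [] for c in classes}
    per_class_conf = {c: [] for c in classes}
    n_gt = {c: 0 for c in classes}
    for c in classes:
        res.tp[c] = res.fp[c] = res.fn[c] = 0
    for dets, gts in zip(detections_per_image, gts_per_image):
        for c in classes:
            cdets = [d for d in dets if d.class_id == c]
            cgts = [g for g in gts if g.class_id == c]
            sorted_dets, flags, fn = match_detections(cdets, cgts, iou_threshold)
            res.tp[c] += sum(flags)
            res.fp[c] += len(flags) - sum(flags)
            res.fn[c] += fn
            n_gt[c] += len(cgts)
            per_class_flags[c].extend(flags)
            per_class_conf[c].extend(d.confidence for d in sorted_dets)
    for c in classes:
        res.precision[c], res.recall[c], res.f1[c] = precision_recall_f1(
            res.tp[c], res.fp[c], res.fn[c])
        if n_gt[c] >= 1:
            ap, curve = average_precision(
                per_class_flags[c], per_class_conf[c], n_gt[c],
                interpolation=interpolation, return_curve=True)
            res.ap_per_class[c] = ap
            res.pr_curve[c] = curve
    res.map_value = mean_ap(res.ap_per_class) if res.ap_per_class else 0.0
    return res
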