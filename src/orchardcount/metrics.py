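"""Detection evaluation metrics.

All rates are reported on the percent scale (0-100) with one-decimal rounding
in reports, matching field practice.  True negatives are ill-defined for pure
detection, so FPR is only computed when the caller supplies a
negative-candidate count; otherwise it is withheld (returned as ``None``)
rather than approximated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boxes import BoundingBox, iou_matrix

__all__ = [
    "ConfusionCounts",
    "match_to_truth",
    "precision",
    "recall",
    "f1",
    "fpr",
    "fnr",
    "average_precision",
    "mean_ap",
]

log = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        tn = None
        if self.tn is not None and other.tn is not None:
            tn = self.tn + other.tn
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, tn)


def match_to_truth(detections: Sequence[BoundingBox], truths: Sequence[BoundingBox],
                   iou_min: float = 0.5) -> ConfusionCounts:
    """Greedy highest-IOU one-to-one matching of detections to ground truth.

    Matched pairs are TP, unmatched detections FP, unmatched truths FN.
    """
    if not detections:
        return ConfusionCounts(tp=0, fp=0, fn=len(truths))
    if not truths:
        return ConfusionCounts(tp=0, fp=len(detections), fn=0)
    m = iou_matrix(detections, truths)
    used_d: set[int] = set()
    used_t: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(m, axis=None)[::-1], m.shape))[0]
    tp = 0
    for di, ti in order:
        if m[di, ti] < iou_min:
            break
        if di in used_d or ti in used_t:
            continue
        used_d.add(int(di))
        used_t.add(int(ti))
        tp += 1
    return ConfusionCounts(tp=tp, fp=len(detections) - tp, fn=len(truths) - tp)


def _pct(num: float, den: float, name: str) -> float | None:
    if den <= 0:
        warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
        return None
    return 100.0 * num / den


def precision(c: ConfusionCounts) -> float | None:
    """TP / (TP + FP), percent."""
    return _pct(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float | None:
    """TP / (TP + FN), percent."""
    return _pct(c.tp, c.tp + c.fn, "recall")


def f1(p: float | ConfusionCounts, r: float | None = None) -> float | None:
    """Harmonic mean of precision and recall, percent.

    Accepts either a :class:`ConfusionCounts` or explicit percent-scale
    precision/recall values (as printed in evaluation tables).
    """
    if isinstance(p, ConfusionCounts):
        pv, rv = precision(p), recall(p)
    else:
        pv, rv = p, r
    if pv is None or rv is None:
        return None
    if pv + rv == 0:
        warnings.warn("f1 undefined: precision + recall = 0", stacklevel=2)
        return None
    return 2.0 * pv * rv / (pv + rv)


def fpr(c: ConfusionCounts) -> float | None:
    """FP / (FP + TN), percent; requires a negative-candidate (TN) count."""
    if c.tn is None:
        log.info("FPR withheld: no true-negative candidate count supplied")
        return None
    return _pct(c.fp, c.fp + c.tn, "fpr")


def fnr(c: ConfusionCounts) -> float | None:
    """FN / (FN + TP), percent; identically 100 - recall."""
    return _pct(c.fn, c.fn + c.tp, "fnr")


def average_precision(pr_curve: Sequence[tuple[float, float]]) -> float | None:
    """Trapezoidal area under a precision-recall curve, percent.

    ``pr_curve`` is a sequence of (recall, precision) points on the [0, 1]
    scale, obtained by sweeping the confidence threshold.  The curve is sorted
    by recall and anchored at recall 0 with its first precision value.
    """
    if not pr_curve:
        warnings.warn("average_precision undefined: empty curve", stacklevel=2)
        return None
    pts = sorted({(float(r), float(p)) for r, p in pr_curve})
    rs = [r for r, _ in pts]
    ps = [p for _, p in pts]
    if rs[0] > 0.0:
        rs.insert(0, 0.0)
        ps.insert(0, ps[0])
    return 100.0 * float(np.trapezoid(ps, rs))


def mean_ap(ap_list: Sequence[float], weights: Sequence[float] | None = None) -> float | None:
    """(Optionally count-weighted) mean of per-category average precisions."""
    if not len(ap_list):
        warnings.warn("mean_ap undefined: no AP values", stacklevel=2)
        return None
    return float(np.average(np.asarray(ap_list, dtype=float), weights=weights))
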