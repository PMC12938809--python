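"""Detection and circle-accuracy evaluation.

Standard object-detection metrics (IoU, precision/recall/F1, all-points AP,
mAP over the two classes) plus the circle-level summaries used to evaluate
the refinement pipeline: normalized center/radius errors, Mean/Std/Median/
P95/Max summaries, and tolerance-accuracy curves (fraction of cases whose
normalized error falls below each tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .geometry import Circle, ImageDims
from .roi import RoiBox

__all__ = [
    "MatchCounts",
    "PrCurve",
    "ErrorSummary",
    "iou",
    "match_detections",
    "precision_recall_f1",
    "average_precision",
    "mean_ap",
    "tolerance_accuracy_curve",
    "error_summary",
    "normalized_center_error",
    "normalized_radius_error",
]


class EmptyInputError(ValueError):
    """Raised for empty metric inputs."""


@dataclass(frozen=True)
class MatchCounts:
    """TP/FP/FN at one confidence threshold and IoU threshold."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class PrCurve:
    """Precision-recall points ordered by recall, with the area under them."""

    points: tuple[tuple[float, float], ...]
    ap: float


@dataclass(frozen=True)
class ErrorSummary:
    """Mean/Std/Median/P95/Max summary of an error sample."""

    mean: float
    std: float
    median: float
    p95: float
    max: float


def iou(a: RoiBox, b: RoiBox) -> float:
    """Intersection-over-union of two pixel boxes, in [0, 1]."""
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def match_detections(
    preds: Sequence[RoiBox],
    truths: Sequence[RoiBox],
    conf_t: float = 0.0,
    iou_tau: float = 0.5,
) -> MatchCounts:
    """Greedy one-to-one matching in descending confidence, per class.

    A prediction above the confidence threshold is a TP when its IoU with an
    unmatched same-class truth exceeds ``iou_tau``; otherwise an FP.  Unmatched
    truths are FNs.
    """
    if not (0.0 <= conf_t <= 1.0 and 0.0 <= iou_tau <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    tp = fp = 0
    matched: set[int] = set()
    order = sorted(
        (p for p in preds if p.confidence >= conf_t),
        key=lambda p: -p.confidence,
    )
    for p in order:
        best_j, best_iou = -1, iou_tau
        for j, t in enumerate(truths):
            if j in matched or t.cls != p.cls:
                continue
            v = iou(p, t)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched.add(best_j)
            tp += 1
        else:
            fp += 1
    fn = len(truths) - len(matched)
    return MatchCounts(tp=tp, fp=fp, fn=fn)


def precision_recall_f1(m: MatchCounts) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean; zero-denominator cases → 0."""
    p = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else 0.0
    r = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else 0.0
    f1 = 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def average_precision(
    scored: Sequence[tuple[float, bool]], n_truth: int
) -> PrCurve:
    """All-points (continuous) average precision.

    ``scored`` is a list of (confidence, is_tp) detections; ``n_truth`` the
    number of ground-truth objects.  Detections are swept in descending
    confidence and precision is integrated over recall (trapezoid-free exact
    step integration: each new TP contributes precision-at-that-rank times the
    recall increment).
    """
    if n_truth < 0:
        raise ValueError("n_truth must be >= 0")
    if n_truth == 0 or not scored:
        return PrCurve(points=(), ap=0.0)
    order = sorted(range(len(scored)), key=lambda i: -scored[i][0])
    tp = fp = 0
    points: list[tuple[float, float]] = []
    ap = 0.0
    prev_recall = 0.0
    for i in order:
        if scored[i][1]:
            tp += 1
        else:
            fp += 1
        precision = tp / (tp + fp)
        recall = tp / n_truth
        points.append((recall, precision))
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return PrCurve(points=tuple(points), ap=ap)


def mean_ap(aps: Sequence[float]) -> float:
    """Arithmetic mean of per-class AP values."""
    if len(aps) == 0:
        raise EmptyInputError("no per-class AP values")
    return float(np.mean(aps))


def tolerance_accuracy_curve(
    errors: Sequence[float], tolerances: Sequence[float]
) -> list[tuple[float, float]]:
    """Fraction of errors at or below each tolerance (monotone in tolerance)."""
    errs = np.asarray(errors, dtype=float)
    if errs.size == 0:
        raise EmptyInputError("no errors supplied")
    if any(b < a for a, b in zip(tolerances, tolerances[1:])):
        raise ValueError("tolerances must be sorted ascending")
    return [(float(t), float(np.mean(errs <= t))) for t in tolerances]


def error_summary(errors: Sequence[float]) -> ErrorSummary:
    """Mean, sample std, median, interpolated P95 and max of an error sample."""
    errs = np.asarray(errors, dtype=float)
    if errs.size == 0:
        raise EmptyInputError("no errors supplied")
    std = float(np.std(errs, ddof=1)) if errs.size > 1 else 0.0
    return ErrorSummary(
        mean=float(np.mean(errs)),
        std=std,
        median=float(np.median(errs)),
        p95=float(np.percentile(errs, 95)),  # linear interpolation
        max=float(np.max(errs)),
    )


def normalized_center_error(pred: Circle, truth: Circle, dims: ImageDims) -> float:
    """Euclidean center error divided by the mean image dimension (W+H)/2."""
    d = float(np.hypot(pred.cx - truth.cx, pred.cy - truth.cy))
    return d / dims.mean_dim


def normalized_radius_error(pred: Circle, truth: Circle, dims: ImageDims) -> float:
    """|radius error| divided by the mean image dimension (W+H)/2."""
    return abs(pred.r - truth.r) / dims.mean_dim
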