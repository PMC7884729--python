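"""Pixel- and particle-level evaluation of segmentation and picking.

Pixel metrics come from the 4x4 confusion matrix between a predicted and
a ground-truth class mask (precision = TP/(TP+FP), recall = TP/(TP+FN),
IoU = TP/(TP+FP+FN), with the 0/0 convention mapping to 0).  Particle
metrics use one-to-one greedy matching of predicted to true centres by
ascending distance with a pixel tolerance.  Precision-recall curves are
swept over a score threshold grid; average precision uses the rectangle
sum AP = sum_n (R_n - R_{n-1}) P_n, and a trapezoidal area under the PR
curve is provided separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import ClassMask, ParticleSet, N_CLASSES

__all__ = [
    "PRCurve",
    "MetricsReport",
    "pixel_metrics",
    "f1_score",
    "particle_match",
    "pr_curve",
    "average_precision",
    "pr_auc",
]


@dataclass
class PRCurve:
    """Precision/recall swept over an ascending threshold grid."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    counts: list[tuple[int, int, int]]  # (TP, FP, FN) per threshold

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        self.recall = np.asarray(self.recall, dtype=float)
        n = len(self.thresholds)
        if not (len(self.precision) == len(self.recall) == len(self.counts) == n):
            raise ValueError("PRCurve fields must have equal length")
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be ascending")

    @property
    def f1(self) -> np.ndarray:
        return np.array(
            [f1_score(p, r) for p, r in zip(self.precision, self.recall)]
        )


@dataclass
class MetricsReport:
    """Per-class and aggregate pixel metrics (all values in [0, 1])."""

    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    iou: dict[int, float]
    accuracy: float
    mean_iou: float

    def as_dict(self) -> dict:
        return {
            "precision": {int(k): v for k, v in self.precision.items()},
            "recall": {int(k): v for k, v in self.recall.items()},
            "f1": {int(k): v for k, v in self.f1.items()},
            "iou": {int(k): v for k, v in self.iou.items()},
            "accuracy": self.accuracy,
            "mean_iou": self.mean_iou,
        }


def _safe_div(num: float, den: float) -> float:
    """0/0 -> 0 convention for metric ratios."""
    return num / den if den > 0 else 0.0


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must be in [0, 1]")
    return _safe_div(2.0 * precision * recall, precision + recall)


def pixel_metrics(pred: ClassMask, truth: ClassMask) -> MetricsReport:
    """Per-class precision/recall/F1/IoU plus accuracy and mean IoU.

    Mean IoU averages (unweighted) over the classes present in the truth.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.labels.ravel().astype(np.int64)
    t = truth.labels.ravel().astype(np.int64)
    confusion = np.bincount(t * N_CLASSES + p, minlength=N_CLASSES * N_CLASSES)
    confusion = confusion.reshape(N_CLASSES, N_CLASSES)  # [truth, pred]
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    precision = {c: _safe_div(tp[c], tp[c] + fp[c]) for c in range(N_CLASSES)}
    recall = {c: _safe_div(tp[c], tp[c] + fn[c]) for c in range(N_CLASSES)}
    f1 = {c: f1_score(precision[c], recall[c]) for c in range(N_CLASSES)}
    iou = {c: _safe_div(tp[c], tp[c] + fp[c] + fn[c]) for c in range(N_CLASSES)}
    present = [c for c in range(N_CLASSES) if confusion[c].sum() > 0]
    mean_iou = float(np.mean([iou[c] for c in present])) if present else 0.0
    accuracy = _safe_div(tp.sum(), confusion.sum())
    return MetricsReport(
        precision=precision, recall=recall, f1=f1, iou=iou,
        accuracy=accuracy, mean_iou=mean_iou,
    )


def particle_match(
    pred: ParticleSet, truth: ParticleSet, tol_px: float
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """One-to-one greedy matching of predicted to true centres.

    Candidate pairs within ``tol_px`` are matched in ascending distance
    order; each prediction and each truth may be used once.  Returns
    (TP, FP, FN, matches) where matches is a list of (pred_idx, truth_idx).
    """
    if tol_px <= 0:
        raise ValueError("tol_px must be > 0")
    pc = np.asarray(pred.centers, dtype=float).reshape(-1, 2)
    tc = np.asarray(truth.centers, dtype=float).reshape(-1, 2)
    if len(pc) == 0 or len(tc) == 0:
        return 0, len(pc), len(tc), []
    d = np.hypot(pc[:, None, 0] - tc[None, :, 0], pc[:, None, 1] - tc[None, :, 1])
    pairs = np.argwhere(d <= tol_px)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[int, int]] = []
    for pi, ti in pairs[order]:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(int(pi))
        used_t.add(int(ti))
        matches.append((int(pi), int(ti)))
    tp = len(matches)
    return tp, len(pc) - tp, len(tc) - tp, matches


def pr_curve(
    pred: ParticleSet,
    truth: ParticleSet,
    tol_px: float,
    grid: Sequence[float],
) -> PRCurve:
    """Particle-level PR curve from a scored prediction set.

    At each grid threshold ``t`` the predictions with score >= t are
    matched against the truth.  The truth must be non-empty (recall is
    otherwise undefined).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be ascending")
    if len(truth) == 0:
        raise ValueError("empty truth: recall undefined")
    if pred.scores is None:
        raise ValueError("pred must carry per-particle scores")
    precisions, recalls, counts = [], [], []
    for t in grid:
        keep = pred.scores >= t
        sub = ParticleSet(
            centers=pred.centers[keep],
            radius_px=pred.radius_px,
            image_shape=pred.image_shape,
            scores=pred.scores[keep],
        )
        tp, fp, fn, _ = particle_match(sub, truth, tol_px)
        precisions.append(_safe_div(tp, tp + fp))
        recalls.append(_safe_div(tp, tp + fn))
        counts.append((tp, fp, fn))
    return PRCurve(
        thresholds=grid, precision=np.array(precisions),
        recall=np.array(recalls), counts=counts,
    )


def average_precision(curve: PRCurve) -> float:
    """Rectangle-sum AP: sum over points of (R_n - R_{n-1}) * P_n.

    Points are taken in ascending-recall order with R_0 = 0 prepended.
    """
    order = np.argsort(curve.recall, kind="stable")
    r = curve.recall[order]
    p = curve.precision[order]
    r_prev = 0.0
    ap = 0.0
    for rn, pn in zip(r, p):
        ap += (rn - r_prev) * pn
        r_prev = rn
    return float(np.clip(ap, 0.0, 1.0))


def pr_auc(curve: PRCurve) -> float:
    """Trapezoidal area under precision vs recall, clamped to the unit box."""
    if len(curve.recall) < 2:
        raise ValueError("need >= 2 points for a trapezoidal area; "
                         "use average_precision for a single point")
    order = np.argsort(curve.recall, kind="stable")
    r = np.clip(curve.recall[order], 0.0, 1.0)
    p = np.clip(curve.precision[order], 0.0, 1.0)
    return float(np.trapezoid(p, r))
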