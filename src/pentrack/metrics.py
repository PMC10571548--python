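"""Detection-evaluation formulas: IoU, greedy matching, precision/recall, AP/mAP.

AP uses all-point interpolation (area under the precision envelope), and mAP
is the arithmetic mean of per-class APs.  ``mAP@0.5`` is obtained by matching
at an IoU threshold of 0.5.  Evaluation is pooled per class over the whole
stream; when frame indices are available, matching is constrained within each
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import Box, Detection, FrameStream, ObjectClass

__all__ = [
    "EvaluationError",
    "MatchFlags",
    "PRCurve",
    "DetectionMetrics",
    "box_iou",
    "iou_matrix",
    "match_detections",
    "precision_recall",
    "average_precision",
    "average_precision_map",
    "evaluate_detections",
]


class EvaluationError(RuntimeError):
    """Raised when a metric is undefined for the given inputs."""


def box_iou(a: Box, b: Box) -> float:
    """Intersection area over union area of two boxes; 0 when disjoint."""
    iw = min(a.x2, b.x2) - max(a.x1, b.x1)
    ih = min(a.y2, b.y2) - max(a.y1, b.y1)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def iou_matrix(rows: Sequence[Box], cols: Sequence[Box]) -> np.ndarray:
    """Pairwise IoU, shape (len(rows), len(cols))."""
    if not rows or not cols:
        return np.zeros((len(rows), len(cols)))
    ra = np.array([(b.x1, b.y1, b.x2, b.y2) for b in rows])
    ca = np.array([(b.x1, b.y1, b.x2, b.y2) for b in cols])
    iw = np.minimum(ra[:, None, 2], ca[None, :, 2]) - np.maximum(
        ra[:, None, 0], ca[None, :, 0]
    )
    ih = np.minimum(ra[:, None, 3], ca[None, :, 3]) - np.maximum(
        ra[:, None, 1], ca[None, :, 1]
    )
    inter = np.clip(iw, 0.0, None) * np.clip(ih, 0.0, None)
    area_r = (ra[:, 2] - ra[:, 0]) * (ra[:, 3] - ra[:, 1])
    area_c = (ca[:, 2] - ca[:, 0]) * (ca[:, 3] - ca[:, 1])
    return inter / (area_r[:, None] + area_c[None, :] - inter)


@dataclass
class MatchFlags:
    """Per-detection TP/FP flags ordered by descending score, plus GT count."""

    scores: np.ndarray
    is_tp: np.ndarray
    n_gt: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.is_tp = np.asarray(self.is_tp, dtype=bool)
        if self.scores.shape != self.is_tp.shape:
            raise EvaluationError("scores and flags length mismatch")
        if np.any(np.diff(self.scores) > 0):
            raise EvaluationError("scores must be non-increasing")
        if int(self.is_tp.sum()) > self.n_gt:
            raise EvaluationError("more TP flags than ground-truth boxes")

    @classmethod
    def merge(cls, parts: Sequence["MatchFlags"]) -> "MatchFlags":
        """Pool flags from several disjoint matchings (e.g. per frame)."""
        if not parts:
            return cls(np.array([]), np.array([], dtype=bool), 0)
        scores = np.concatenate([p.scores for p in parts])
        flags = np.concatenate([p.is_tp for p in parts])
        order = np.argsort(-scores, kind="stable")
        return cls(scores[order], flags[order], sum(p.n_gt for p in parts))


def match_detections(
    preds: Sequence[Detection],
    gts: Sequence[Box],
    iou_thresh: float,
) -> MatchFlags:
    """Greedy confidence-ordered one-to-one matching of predictions to GT.

    Predictions are visited in descending score (ties broken by input
    order); each is a TP if its best-IoU still-unmatched ground truth has
    IoU >= ``iou_thresh``, which then becomes matched, otherwise an FP.
    """
    if not 0.0 < iou_thresh < 1.0:
        raise EvaluationError(f"iou_thresh must be in (0, 1), got {iou_thresh}")
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    ious = iou_matrix([preds[i].box for i in order], list(gts))
    taken = np.zeros(len(gts), dtype=bool)
    flags = np.zeros(len(preds), dtype=bool)
    for k in range(len(order)):
        if len(gts) == 0:
            break
        row = np.where(taken, -1.0, ious[k])
        j = int(np.argmax(row))
        if row[j] >= iou_thresh:
            taken[j] = True
            flags[k] = True
    scores = np.array([preds[i].score for i in order])
    return MatchFlags(scores, flags, len(gts))


@dataclass
class PRCurve:
    """Cumulative (recall, precision) points after each detection."""

    recall: np.ndarray
    precision: np.ndarray

    def __post_init__(self) -> None:
        self.recall = np.asarray(self.recall, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if self.recall.shape != self.precision.shape:
            raise EvaluationError("recall and precision length mismatch")
        if np.any(np.diff(self.recall) < 0):
            raise EvaluationError("recall must be non-decreasing")

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.recall.tolist(), self.precision.tolist()))


def precision_recall(flags: MatchFlags) -> PRCurve:
    """Cumulative precision TP_k/(TP_k+FP_k) and recall TP_k/n_gt."""
    if flags.n_gt == 0:
        raise EvaluationError("recall undefined: no ground-truth boxes")
    tp = np.cumsum(flags.is_tp)
    k = np.arange(1, len(flags.is_tp) + 1)
    return PRCurve(tp / flags.n_gt, tp / k)


def average_precision(curve: PRCurve) -> float:
    """Area under the precision envelope (all-point interpolation).

    At each recall the envelope takes the maximum precision attained at any
    recall >= it; AP is the integral of that envelope over recall.
    """
    if len(curve.recall) == 0:
        return 0.0
    mrec = np.concatenate([[0.0], curve.recall])
    mpre = np.concatenate([[0.0], curve.precision])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    return float(np.sum(np.diff(mrec) * mpre[1:]))


@dataclass
class DetectionMetrics:
    """Per-class AP and their mean, at a fixed IoU matching threshold."""

    ap: dict[str, float]
    iou_threshold: float
    map: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.ap:
            raise EvaluationError("at least one class is required")
        for name, v in self.ap.items():
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise EvaluationError(f"AP for {name} outside [0, 1]: {v}")
        self.map = float(np.mean(list(self.ap.values())))


def average_precision_map(
    curves: Mapping[ObjectClass | str, PRCurve],
    iou_threshold: float = 0.5,
) -> DetectionMetrics:
    """Per-class AP from PR curves, and their arithmetic mean (mAP)."""
    ap = {
        (c.value if isinstance(c, ObjectClass) else str(c)): average_precision(curve)
        for c, curve in curves.items()
    }
    return DetectionMetrics(ap=ap, iou_threshold=iou_threshold)


def evaluate_detections(
    pred: FrameStream,
    gt: FrameStream,
    iou_thresh: float = 0.5,
    classes: Sequence[ObjectClass] = (ObjectClass.PIG, ObjectClass.PIG_FIGHTING),
) -> DetectionMetrics:
    """Pooled per-class evaluation of a prediction stream against ground truth.

    Matching is constrained within each frame; flags are then pooled per
    class over all frames.  Classes absent from the ground truth are skipped
    (their recall would be undefined).
    """
    curves: dict[ObjectClass, PRCurve] = {}
    for cls in classes:
        parts = []
        frames = sorted(
            set(pred.restrict(cls).frame_indices) | set(gt.restrict(cls).frame_indices)
        )
        n_gt_total = 0
        for f in frames:
            p = [d for d in pred.at(f) if d.cls is cls]
            g = [d.box for d in gt.at(f) if d.cls is cls]
            n_gt_total += len(g)
            parts.append(match_detections(p, g, iou_thresh))
        if n_gt_total == 0:
            continue
        curves[cls] = precision_recall(MatchFlags.merge(parts))
    if not curves:
        raise EvaluationError("no ground-truth boxes for any requested class")
    return average_precision_map(curves, iou_threshold=iou_thresh)
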