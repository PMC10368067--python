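"""Classification and detection scoring.

Classification uses accuracy, sensitivity and specificity from a confusion
table.  Detection follows the point-annotation convention: ground truth is
a set of points, predictions a labeled mask (boxes are rasterized first);
a predicted component containing at least one point is a true positive,
surplus points inside an already-matched component count as false
negatives (penalizing merged detections), empty components are false
positives, and unmatched points are false negatives.  Precision, recall
and F1 = 2TP / (2TP + FP + FN) follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "ClassificationMetrics",
    "DetectionScore",
    "classification_metrics",
    "match_points_to_masks",
    "detection_metrics",
    "match_centroids",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Metrics are None when their denominator is zero (undefined, not 0)."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None


@dataclass(frozen=True)
class DetectionScore:
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None


def classification_metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    if counts.total == 0:
        raise ValueError("confusion counts are all zero")
    acc = (counts.tp + counts.tn) / counts.total
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp > 0 else None
    return ClassificationMetrics(accuracy=acc, sensitivity=sens, specificity=spec)


def match_points_to_masks(gt_points: np.ndarray, labeled_mask: np.ndarray, n_labels: int | None = None) -> ConfusionCounts:
    """Match point annotations against predicted components.

    ``gt_points`` is (m, d) with d matching the mask dimensionality, in
    (row, col) / (z, y, x) order; points are assigned to the component of
    their nearest voxel.  Returns tp/fp/fn counts (tn is meaningless here).
    """
    labels = np.asarray(labeled_mask)
    pts = np.asarray(gt_points, dtype=float).reshape(-1, labels.ndim)
    if n_labels is None:
        n_labels = int(labels.max())
    if pts.size and (np.any(pts < -0.5) or np.any(pts > np.asarray(labels.shape) - 0.5)):
        raise ValueError("ground-truth point outside mask bounds")
    hits: dict[int, int] = {}
    unmatched_points = 0
    for p in pts:
        idx = tuple(int(round(c)) for c in np.clip(p, 0, np.asarray(labels.shape) - 1))
        lab = int(labels[idx])
        if lab == 0:
            unmatched_points += 1
        else:
            hits[lab] = hits.get(lab, 0) + 1
    tp = len(hits)
    fn = unmatched_points + sum(c - 1 for c in hits.values())
    fp = n_labels - tp
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def detection_metrics(tp: int, fp: int, fn: int) -> DetectionScore:
    if tp + fp == 0 and tp + fn == 0:
        raise ValueError("no predictions and no ground truth: metrics undefined")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else None
    return DetectionScore(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)


def match_centroids(
    gt: np.ndarray,
    pred: np.ndarray,
    tolerance: float,
) -> DetectionScore:
    """Greedy one-to-one centroid matching by ascending distance within
    ``tolerance``; used to score detections against planted ground truth."""
    gt = np.asarray(gt, dtype=float).reshape(-1, np.asarray(gt).shape[-1] if np.asarray(gt).size else 2)
    pred = np.asarray(pred, dtype=float).reshape(-1, gt.shape[1] if gt.size else 2)
    if gt.size == 0 and pred.size == 0:
        raise ValueError("no predictions and no ground truth: metrics undefined")
    if gt.size == 0 or pred.size == 0:
        return detection_metrics(0, pred.shape[0], gt.shape[0])
    d = np.linalg.norm(gt[:, None, :] - pred[None, :, :], axis=-1)
    pairs = [(d[i, j], i, j) for i in range(d.shape[0]) for j in range(d.shape[1]) if d[i, j] <= tolerance]
    pairs.sort()
    used_g: set[int] = set()
    used_p: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_g or j in used_p:
            continue
        used_g.add(i)
        used_p.add(j)
        tp += 1
    return detection_metrics(tp, pred.shape[0] - tp, gt.shape[0] - tp)
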