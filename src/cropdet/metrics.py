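"""Detection evaluation: precision, recall, average precision, mAP and the
confusion matrix.

Matching is greedy in descending score order: a detection is a true
positive iff it shares the class of a not-yet-matched ground-truth box and
overlaps it with IoU at or above the threshold (ties broken by highest
IoU); every ground truth can absorb at most one detection.  AP is the
101-point interpolated area under the precision-recall curve (precision at
recall r is the maximum precision at any recall >= r, sampled on the grid
0, 0.01, ..., 1), and mAP averages per-class AP over the IoU thresholds
0.50, 0.55, ..., 0.95.  Classes with no ground-truth instances are left
out of the means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import Box
from .losses import iou as box_iou

IOU_THRESHOLDS = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


@dataclass
class DetectionRecord:
    """Predictions for one image: parallel arrays of boxes (xyxy), integer
    labels and scores, kept sorted by descending score."""

    boxes: np.ndarray    # (n, 4) xyxy
    labels: np.ndarray   # (n,) int
    scores: np.ndarray   # (n,) float

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=float).reshape(-1, 4)
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
        order = np.argsort(-self.scores, kind="stable")
        self.boxes, self.labels, self.scores = (
            self.boxes[order], self.labels[order], self.scores[order])

    def __len__(self):
        return len(self.scores)

    @staticmethod
    def from_boxes(boxes: list[Box]) -> "DetectionRecord":
        if not boxes:
            return DetectionRecord(np.zeros((0, 4)), np.zeros(0, int), np.zeros(0))
        return DetectionRecord(
            np.stack([b.as_xyxy() for b in boxes]),
            np.array([b.label for b in boxes]),
            np.array([b.score if b.score is not None else 1.0 for b in boxes]))


@dataclass
class GroundTruth:
    boxes: np.ndarray    # (m, 4) xyxy
    labels: np.ndarray   # (m,) int

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=float).reshape(-1, 4)
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)

    def __len__(self):
        return len(self.labels)


@dataclass
class MatchResult:
    det_is_tp: np.ndarray     # (n,) bool, aligned with score-sorted dets
    gt_matched: np.ndarray    # (m,) bool
    tp: int
    fp: int
    fn: int


@dataclass
class EvalResult:
    per_class_ap: dict[int, dict[float, float]]
    ap50: float
    map: float
    precision: float
    recall: float
    confusion: np.ndarray | None = None
    class_ids: tuple = ()

    def as_dict(self) -> dict:
        return {
            "AP50": self.ap50,
            "mAP": self.map,
            "precision": self.precision,
            "recall": self.recall,
            "per_class_ap": {str(k): {f"{t:.2f}": v for t, v in d.items()}
                             for k, d in self.per_class_ap.items()},
        }


def _pair_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU between every row of a (n,4) and b (m,4)."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def match_detections(dets: DetectionRecord, gts: GroundTruth,
                     iou_threshold: float = 0.5,
                     class_agnostic: bool = False) -> MatchResult:
    """Greedy score-ordered matching of detections to ground truth."""
    n, m = len(dets), len(gts)
    det_tp = np.zeros(n, dtype=bool)
    gt_used = np.zeros(m, dtype=bool)
    det_match = np.full(n, -1, dtype=int)
    ious = _pair_iou_matrix(dets.boxes, gts.boxes)
    for i in range(n):
        best_j, best_iou = -1, iou_threshold
        for j in range(m):
            if gt_used[j]:
                continue
            if not class_agnostic and dets.labels[i] != gts.labels[j]:
                continue
            if ious[i, j] >= best_iou:
                # strict > keeps the first (highest-IoU) candidate on ties
                if ious[i, j] > best_iou or best_j == -1:
                    best_j, best_iou = j, ious[i, j]
        if best_j >= 0:
            det_tp[i] = True
            gt_used[best_j] = True
            det_match[i] = best_j
    tp = int(det_tp.sum())
    res = MatchResult(det_tp, gt_used, tp, n - tp, m - tp)
    res.det_match = det_match
    return res


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN); 0/0 is defined as 0."""
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    return p, r


def average_precision(dets: list[DetectionRecord], gts: list[GroundTruth],
                      iou_threshold: float = 0.5,
                      interpolation: str = "101point") -> float:
    """AP of a single class over a set of images.

    `dets` and `gts` are parallel per-image lists already restricted to one
    class.  Returns the interpolated area under the P-R curve; with no
    ground truth the value is undefined and NaN is returned so callers can
    exclude the class from means.
    """
    n_gt = sum(len(g) for g in gts)
    if n_gt == 0:
        return float("nan")
    scores, flags = [], []
    for d, g in zip(dets, gts):
        res = match_detections(d, g, iou_threshold)
        scores.append(d.scores)
        flags.append(res.det_is_tp)
    scores = np.concatenate(scores) if scores else np.zeros(0)
    flags = np.concatenate(flags) if flags else np.zeros(0, bool)
    order = np.argsort(-scores, kind="stable")
    flags = flags[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    if interpolation == "101point":
        grid = np.linspace(0, 1, 101)
        # precision envelope: max precision at recall >= r
        env = np.maximum.accumulate(precision[::-1])[::-1]
        ap = 0.0
        for r in grid:
            idx = np.searchsorted(recall, r, side="left")
            ap += env[idx] if idx < len(env) else 0.0
        return float(ap / 101.0)
    if interpolation == "continuous":
        mrec = np.concatenate([[0.0], recall, [1.0]])
        mpre = np.concatenate([[0.0], precision, [0.0]])
        mpre = np.maximum.accumulate(mpre[::-1])[::-1]
        idx = np.where(mrec[1:] != mrec[:-1])[0]
        return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def mean_ap(per_class_ap: dict[int, dict[float, float]],
            thresholds=IOU_THRESHOLDS) -> tuple[float, float]:
    """(AP50, mAP): means over classes at IoU 0.5, and over classes and the
    ten thresholds.  NaN entries (classes without ground truth) are skipped."""
    at50 = [d[0.5] for d in per_class_ap.values() if not np.isnan(d[0.5])]
    all_vals = [v for d in per_class_ap.values()
                for t, v in d.items() if t in thresholds and not np.isnan(v)]
    ap50 = float(np.mean(at50)) if at50 else 0.0
    m = float(np.mean(all_vals)) if all_vals else 0.0
    return ap50, m


def confusion_matrix(dets: list[DetectionRecord], gts: list[GroundTruth],
                     num_classes: int, iou_threshold: float = 0.5,
                     score_threshold: float = 0.25) -> np.ndarray:
    """(m+1) x (m+1) counts; rows are actual classes, columns predicted.

    Matching is class-agnostic at the given IoU; unmatched ground truths
    count in the background column (last), unmatched detections in the
    background row.
    """
    cm = np.zeros((num_classes + 1, num_classes + 1), dtype=int)
    bg = num_classes
    for d, g in zip(dets, gts):
        keep = d.scores >= score_threshold
        dk = DetectionRecord(d.boxes[keep], d.labels[keep], d.scores[keep])
        res = match_detections(dk, g, iou_threshold, class_agnostic=True)
        for i in range(len(dk)):
            j = res.det_match[i]
            if j >= 0:
                cm[g.labels[j], dk.labels[i]] += 1
            else:
                cm[bg, dk.labels[i]] += 1
        for j in range(len(g)):
            if not res.gt_matched[j]:
                cm[g.labels[j], bg] += 1
    return cm


def evaluate(dets: list[DetectionRecord], gts: list[GroundTruth],
             num_classes: int, thresholds=IOU_THRESHOLDS,
             score_threshold: float = 0.25,
             interpolation: str = "101point") -> EvalResult:
    """Full evaluation across images: per-class AP at each threshold, AP50,
    mAP, dataset precision/recall at IoU 0.5, and the confusion matrix."""
    per_class: dict[int, dict[float, float]] = {}
    for c in range(num_classes):
        dc = [DetectionRecord(d.boxes[d.labels == c], d.labels[d.labels == c],
                              d.scores[d.labels == c]) for d in dets]
        gc = [GroundTruth(g.boxes[g.labels == c], g.labels[g.labels == c])
              for g in gts]
        if sum(len(g) for g in gc) == 0:
            continue
        per_class[c] = {float(t): average_precision(dc, gc, float(t), interpolation)
                        for t in thresholds}
    ap50, m = mean_ap(per_class, thresholds)
    tp = fp = fn = 0
    for d, g in zip(dets, gts):
        keep = d.scores >= score_threshold
        res = match_detections(
            DetectionRecord(d.boxes[keep], d.labels[keep], d.scores[keep]),
            g, 0.5)
        tp += res.tp
        fp += res.fp
        fn += res.fn
    p, r = precision_recall(tp, fp, fn)
    cm = confusion_matrix(dets, gts, num_classes, 0.5, score_threshold)
    return EvalResult(per_class, ap50, m, p, r, cm, tuple(sorted(per_class)))
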