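"""Detection and classification metrics used across the pipeline.

All scores are authored here (IoU, greedy NMS, confusion-derived scores,
Mann-Whitney ROC-AUC, all-points-interpolated average precision, and
single-class mAP@IoU with greedy matching) so the decision rules are
explicit; reference implementations from scikit-learn serve as oracles in
the test-suite only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boxes import Box, Detection, intersection_area

logger = logging.getLogger(__name__)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    inter = intersection_area(a, b)
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def nms(detections: Sequence[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression.

    Detections are visited by descending confidence (ties keep input
    order); a detection is suppressed iff its IoU with an already-kept
    detection exceeds ``iou_threshold``.  Kept detections are returned in
    the visiting order.
    """
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].score, i))
    kept: list[Detection] = []
    for i in order:
        d = detections[i]
        if all(iou(d.box, k.box) <= iou_threshold for k in kept):
            kept.append(d)
    return kept


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(y_true & y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    # 0/0 conventions: undefined ratios are reported as 0 with a log flag.
    if den == 0:
        logger.debug("metric %s undefined (0/0); reporting 0", name)
        return 0.0
    return num / den


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Precision, recall, F1, specificity and accuracy from counts."""
    precision = _safe_ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = _safe_ratio(counts.tp, counts.tp + counts.fn, "recall")
    f1 = _safe_ratio(2 * precision * recall, precision + recall, "f1")
    specificity = _safe_ratio(counts.tn, counts.tn + counts.fp, "specificity")
    accuracy = _safe_ratio(counts.tp + counts.tn, counts.total, "accuracy")
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "specificity": specificity,
        "accuracy": accuracy,
    }


def f1_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return classification_metrics(confusion_from_predictions(y_true, y_pred))["f1"]


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC-AUC in its Mann-Whitney form: P(random pos outscores random neg),
    with ties counted one-half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both labels present")
    from scipy.stats import rankdata

    ranks = rankdata(s)  # mid-ranks handle ties as 1/2
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the PR step curve with all-points interpolation.

    The precision envelope is made monotone non-increasing in recall before
    integration (Pascal-VOC all-points convention).  Requires at least one
    positive.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    if n_pos == 0:
        raise ValueError("average_precision requires at least one positive")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    recall = tp / n_pos
    precision = tp / (tp + fp)
    return _ap_from_pr(recall, precision)


def _ap_from_pr(recall: np.ndarray, precision: np.ndarray) -> float:
    # prepend the (recall=0) anchor, then integrate the monotone envelope
    r = np.concatenate(([0.0], recall))
    p = np.concatenate(([1.0], precision))
    p = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def map_at_iou(
    detections_per_image: Sequence[Sequence[Detection]],
    gt_boxes_per_image: Sequence[Sequence[Box]],
    iou_threshold: float = 0.5,
) -> float:
    """Single-class mean average precision at a fixed IoU threshold.

    Detections are pooled across images and sorted by confidence; each is
    greedily matched to the highest-IoU not-yet-matched ground-truth box of
    its own image (a match requires IoU >= ``iou_threshold``).  Matched
    detections are TPs, the rest FPs; unmatched ground truth counts as FN
    through the recall denominator.  With one foreground class mAP
    reduces to AP.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must be in (0, 1)")
    n_gt = sum(len(g) for g in gt_boxes_per_image)
    if n_gt == 0:
        raise ValueError("map_at_iou requires at least one ground-truth box")
    pooled: list[tuple[float, int, Detection]] = []
    for img_idx, dets in enumerate(detections_per_image):
        for d in dets:
            pooled.append((d.score, img_idx, d))
    if not pooled:
        return 0.0
    pooled.sort(key=lambda t: -t[0])
    matched: list[set[int]] = [set() for _ in gt_boxes_per_image]
    is_tp = np.zeros(len(pooled), dtype=bool)
    for i, (_, img_idx, det) in enumerate(pooled):
        gts = gt_boxes_per_image[img_idx]
        best_j, best_iou = -1, iou_threshold
        for j, g in enumerate(gts):
            if j in matched[img_idx]:
                continue
            v = iou(det.box, g)
            if v > best_iou or (v == best_iou and best_j == -1 and v >= iou_threshold):
                best_j, best_iou = j, v
        if best_j >= 0:
            matched[img_idx].add(best_j)
            is_tp[i] = True
    tp = np.cumsum(is_tp)
    fp = np.cumsum(~is_tp)
    recall = tp / n_gt
    precision = tp / (tp + fp)
    return _ap_from_pr(recall, precision)
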