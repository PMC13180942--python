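"""Detection/classification metrics against hand arithmetic, brute-force
oracles and scikit-learn references."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from roiadj.boxes import Box, Detection
from roiadj.metrics import (
    ConfusionCounts,
    average_precision,
    classification_metrics,
    iou,
    map_at_iou,
    nms,
    roc_auc,
)


def boxes_strategy():
    coord = st.integers(min_value=0, max_value=40)
    side = st.integers(min_value=1, max_value=30)
    return st.builds(
        lambda x, y, w, h: Box(x, y, x + w, y + h), coord, coord, side, side
    )


class TestIoU:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (Box(0, 0, 10, 10), Box(0, 0, 10, 10), 1.0),
            (Box(0, 0, 10, 10), Box(20, 20, 30, 30), 0.0),
            (Box(0, 0, 10, 10), Box(5, 0, 15, 10), 1.0 / 3.0),  # 50 / 150
        ],
    )
    def test_known_values(self, a, b, expected):
        assert iou(a, b) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(boxes_strategy(), boxes_strategy())
    def test_symmetry_and_bounds(self, a, b):
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= min(a.area, b.area) / max(a.area, b.area)


def _nms_bruteforce(dets, thr):
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    kept = []
    for i in order:
        if all(iou(dets[i].box, dets[j].box) <= thr for j in kept):
            kept.append(i)
    return [dets[i] for i in kept]


class TestNms:
    def test_single_detection_kept(self):
        d = Detection(Box(0, 0, 5, 5), 0.9)
        assert nms([d], 0.5) == [d]

    def test_duplicate_keeps_higher_confidence(self):
        a = Detection(Box(0, 0, 10, 10), 0.9)
        b = Detection(Box(0, 0, 10, 10), 0.8)
        assert nms([b, a], 0.5) == [a]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(7)
        dets = [
            Detection(
                Box(x, y, x + w, y + h), float(sc)
            )
            for x, y, w, h, sc in zip(
                rng.integers(0, 30, 50),
                rng.integers(0, 30, 50),
                rng.integers(4, 20, 50),
                rng.integers(4, 20, 50),
                rng.uniform(0.01, 1.0, 50),
            )
        ]
        for thr in (0.2, 0.5, 0.8):
            kept = nms(dets, thr)
            assert kept == _nms_bruteforce(dets, thr)
            # kept set has pairwise IoU <= threshold
            for i, a in enumerate(kept):
                for b in kept[i + 1 :]:
                    assert iou(a.box, b.box) <= thr


class TestClassificationMetrics:
    def test_hand_arithmetic(self):
        m = classification_metrics(ConfusionCounts(tp=2, fp=1, fn=1, tn=6))
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(6 / 7)

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert all(v == 1.0 for v in m.values())

    def test_degenerate_precision_is_zero(self):
        m = classification_metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=7))
        assert m["precision"] == 0.0
        assert m["f1"] == 0.0


class TestRocAuc:
    def test_separated_and_constant(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_single_label_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = rng.choice(np.linspace(0, 1, 20), size=300)  # heavy ties
        labels = rng.integers(0, 2, 300)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-9
        )


def _ap_bruteforce(scores, labels):
    """All-points interpolated AP via the explicit envelope definition."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    n_pos = y.sum()
    recalls, precisions = [0.0], [1.0]
    tp = fp = 0
    for yi in y:
        tp, fp = tp + (yi == 1), fp + (yi == 0)
        recalls.append(tp / n_pos)
        precisions.append(tp / (tp + fp))
    ap = 0.0
    for i in range(1, len(recalls)):
        p_env = max(precisions[j] for j in range(i, len(precisions)))
        ap += (recalls[i] - recalls[i - 1]) * p_env
    return ap


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_three_point_curve_by_hand(self):
        # ranks: (y=1, P=1, R=.5), (y=0, P=.5), (y=1, P=2/3, R=1)
        assert average_precision([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(
            0.5 * 1.0 + 0.5 * (2 / 3)
        )

    def test_no_positives_raises(self):
        with pytest.raises(ValueError):
            average_precision([0.5], [0])

    def test_matches_envelope_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            scores = rng.uniform(0, 1, n)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                labels[0] = 1
            assert average_precision(scores, labels) == pytest.approx(
                _ap_bruteforce(scores, labels), abs=1e-9
            )

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(0, 1, 40)
        labels = rng.integers(0, 2, 40)
        labels[0] = 1
        a = average_precision(scores, labels)
        b = average_precision(np.exp(3 * scores) - 0.5, labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestMapAtIou:
    def test_detections_equal_gt(self):
        gt = [[Box(0, 0, 10, 10), Box(20, 20, 40, 40)], [Box(5, 5, 15, 15)]]
        dets = [
            [Detection(b, c) for b, c in zip(gt[0], (0.3, 0.9))],
            [Detection(gt[1][0], 0.5)],
        ]
        assert map_at_iou(dets, gt, 0.5) == 1.0

    def test_no_detections(self):
        assert map_at_iou([[]], [[Box(0, 0, 10, 10)]], 0.5) == 0.0

    def test_no_ground_truth_raises(self):
        with pytest.raises(ValueError):
            map_at_iou([[Detection(Box(0, 0, 5, 5), 0.9)]], [[]], 0.5)

    def test_duplicate_match_counts_as_fp(self):
        # 2 GT, 3 detections; the duplicate on gt0 must be an FP.
        gt = [[Box(0, 0, 10, 10), Box(30, 0, 40, 10)]]
        dets = [[
            Detection(Box(0, 0, 10, 10), 0.95),   # TP on gt0
            Detection(Box(1, 0, 11, 10), 0.90),   # duplicate on gt0 -> FP
            Detection(Box(30, 0, 40, 10), 0.85),  # TP on gt1
        ]]
        # PR sequence: (1, 1/2), (1/2 -> precision 1/2 at rank 2), rank3 TP:
        # recall 1/2 at p=1, then recall 1 at p=2/3
        expected = 0.5 * 1.0 + 0.5 * (2 / 3)
        assert map_at_iou(dets, gt, 0.5) == pytest.approx(expected)
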