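"""Convex fusion, operating-point selection, calibration and paired
statistics against grid oracles, closed forms and scipy references."""

import numpy as np
import pytest

from roiadj.fuse import (
    bootstrap_ci,
    brier,
    calibration_report,
    ece,
    fuse_scores,
    select_alpha,
    select_threshold,
    wilcoxon_paired,
)
from roiadj.metrics import f1_score


class TestFuseScores:
    def test_default_alpha_arithmetic(self):
        assert fuse_scores(1.0, 0.5, 0.6) == pytest.approx(0.8)

    def test_detector_only_limit(self):
        y_hat = np.array([0.1, 0.9])
        s = np.array([0.3, 0.4])
        assert np.allclose(fuse_scores(y_hat, s, 0.0), s)

    def test_adjudicator_only_limit(self):
        y_hat = np.array([0.1, 0.9])
        s = np.array([0.3, 0.4])
        assert np.allclose(fuse_scores(y_hat, s, 1.0), y_hat)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        y_hat = np.sort(rng.uniform(0, 1, 50))
        s = rng.uniform(0, 1, 1)[0] * np.ones(50)
        fused = fuse_scores(y_hat, s, 0.37)
        assert np.all(np.diff(fused) >= 0)
        assert np.all((fused >= 0) & (fused <= 1))

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fuse_scores(0.5, 0.5, 1.2)


class TestSelectThreshold:
    def test_clean_separation_example(self):
        tau, f1 = select_threshold([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
        assert tau == pytest.approx(0.5)
        assert f1 == 1.0

    def test_all_positive_accepts_everything(self):
        tau, f1 = select_threshold([0.2, 0.8], [1, 1])
        assert (tau, f1) == (0.0, 1.0)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([0.2, 0.8], [0, 0])

    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(1)
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        for _ in range(500):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.uniform(0, 1, n), 3)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                labels[0] = 1
            tau, f1 = select_threshold(scores, labels)
            # vectorized dense-grid F1 scan
            preds = scores[None, :] >= grid[:, None]
            tp = (preds & (labels == 1)).sum(axis=1)
            fp = (preds & (labels == 0)).sum(axis=1)
            fn = ((~preds) & (labels == 1)).sum(axis=1)
            denom = 2 * tp + fp + fn
            grid_f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
            assert f1 == pytest.approx(grid_f1.max(), abs=1e-12)
            assert f1_score(labels, scores >= tau) == pytest.approx(f1)


class TestSelectAlpha:
    def test_predictive_adjudicator_noise_detector(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 120)
        y_hat = 0.8 * y + 0.1 + rng.uniform(-0.05, 0.05, 120)  # separates
        s = rng.uniform(0, 1, 120)  # pure noise
        alpha, tau, f1 = select_alpha(y_hat, s, y)
        assert f1 == 1.0
        # perfect separation must actually hold at the returned pair
        fused = fuse_scores(y_hat, s, alpha)
        assert f1_score(y, fused >= tau) == 1.0

    def test_identical_inputs_tie_break_to_default(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 60)
        scores = rng.uniform(0, 1, 60)
        alpha, _, _ = select_alpha(scores, scores, y)
        assert alpha == pytest.approx(0.6)

    def test_bad_grid_step_rejected(self):
        with pytest.raises(ValueError):
            select_alpha([0.5], [0.5], [1], grid_step=0.7)


class TestCalibration:
    def test_perfectly_confident_and_correct(self):
        assert ece([1.0, 1.0], [1, 1]) == 0.0

    def test_perfectly_confident_and_wrong(self):
        assert ece([1.0, 1.0], [0, 0]) == 1.0

    def test_single_bin_hand_computation(self):
        scores = [0.7] * 10
        labels = [1] * 7 + [0] * 3
        assert ece(scores, labels) == pytest.approx(0.0)

    def test_bin_counts_partition_input(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(0, 1, 137)
        labels = rng.integers(0, 2, 137)
        rep = calibration_report(scores, labels, 10)
        assert sum(rep.bin_counts) == 137

    def test_ece_zero_when_every_bin_calibrated(self):
        # two bins, each with confidence equal to its positive rate
        scores = [0.25, 0.25, 0.25, 0.25, 0.75, 0.75, 0.75, 0.75]
        labels = [1, 0, 0, 0, 1, 1, 1, 0]
        assert ece(scores, labels, n_bins=2) == pytest.approx(0.0)

    def test_brier_closed_forms(self):
        assert brier([1.0, 0.0], [1, 0]) == 0.0
        assert brier([0.5, 0.5], [1, 0]) == 0.25
        assert brier([1.0, 0.0], [0, 1]) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ece([], [])
        with pytest.raises(ValueError):
            brier([], [])


class TestBootstrapCi:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 1, 80)
        labels = rng.integers(0, 2, 80)
        fn = lambda s, y: float(np.mean((s > 0.5) == y))
        a = bootstrap_ci(fn, scores, labels, n_boot=200, seed=7)
        b = bootstrap_ci(fn, scores, labels, n_boot=200, seed=7)
        assert a == b

    def test_degenerate_data_zero_width(self):
        scores = np.full(30, 0.9)
        labels = np.ones(30, dtype=int)
        fn = lambda s, y: float(np.mean(s))
        lo, hi = bootstrap_ci(fn, scores, labels, n_boot=200, seed=0)
        assert lo == hi == pytest.approx(0.9)

    def test_f1_interval_coverage_near_nominal(self):
        # known-parameter simulation: y ~ Bernoulli(p), scores = p
        rng = np.random.default_rng(11)
        p_pool = rng.uniform(0, 1, 200_000)
        y_pool = (rng.uniform(size=200_000) < p_pool).astype(int)
        f1_true = f1_score(y_pool, p_pool >= 0.5)
        fn = lambda s, y: f1_score(y, s >= 0.5)
        hits = 0
        reps = 200
        for r in range(reps):
            p = rng.uniform(0, 1, 500)
            y = (rng.uniform(size=500) < p).astype(int)
            lo, hi = bootstrap_ci(fn, p, y, n_boot=1000, level=0.95, seed=r)
            hits += lo <= f1_true <= hi
        assert abs(hits / reps - 0.95) <= 0.03


class TestWilcoxonPaired:
    def test_exact_small_sample_all_positive(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.zeros(6)
        assert wilcoxon_paired(a, b) == pytest.approx(2 / 64)

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(6)
        b = rng.normal(0, 1, 20)
        a = b + 0.9
        assert wilcoxon_paired(a, b) < 0.05

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.2, 1, 15)
        assert wilcoxon_paired(a, b) == pytest.approx(wilcoxon_paired(b, a))

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1.0, 2.0], [1.0, 2.0])

    def test_large_sample_uses_valid_approximation(self):
        rng = np.random.default_rng(8)
        b = rng.normal(0, 1, 60)
        a = b + rng.normal(0.5, 0.2, 60)
        p = wilcoxon_paired(a, b)
        assert 0.0 <= p < 0.01
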