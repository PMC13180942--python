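"""Adjudicator network: embedding normalization, hand-checked forward
pass, focal-loss closed forms, gradient correctness, training loop
contracts."""

import numpy as np
import pytest

from conftest import make_record
from roiadj import nn
from roiadj.adjnet import (
    AdjudicatorModel,
    TrainConfig,
    adjudicate,
    embed,
    focal_loss,
    focal_loss_grad_logit,
    predict_proba,
    train,
)
from roiadj.boxes import Box


class TestEmbedding:
    def test_three_four_five_triangle(self):
        v = np.array([[3.0, 4.0, 0.0, 0.0]])
        assert np.allclose(nn.l2_normalize(v), [[0.6, 0.8, 0.0, 0.0]])

    def test_unit_vector_unchanged(self):
        v = np.array([[0.0, 1.0, 0.0]])
        assert np.allclose(nn.l2_normalize(v), v)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            nn.l2_normalize(np.zeros((1, 8)))

    def test_embed_returns_unit_norm(self):
        model = AdjudicatorModel(patch_size=16, channels=(4, 8), seed=0)
        rng = np.random.default_rng(1)
        for _ in range(5):
            psi = embed(model, rng.uniform(size=(16, 16)))
            assert np.linalg.norm(psi) == pytest.approx(1.0, abs=1e-6)


class TestAdjudicate:
    def _model(self):
        return AdjudicatorModel(patch_size=8, channels=(4,), hidden=2, seed=0)

    def test_zero_head_gives_half(self):
        m = self._model()
        m.fc1.W[...] = 0.0
        m.fc1.b[...] = 0.0
        m.fc2.W[...] = 0.0
        m.fc2.b[...] = 0.0
        assert adjudicate(m, np.ones((8, 8)), 0.7) == pytest.approx(0.5)

    def test_large_bias_saturates(self):
        m = self._model()
        m.fc2.W[...] = 0.0
        m.fc2.b[...] = 30.0
        assert adjudicate(m, np.ones((8, 8)), 0.2) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_confidence_rejected(self):
        with pytest.raises(ValueError):
            adjudicate(self._model(), np.ones((8, 8)), 1.5)

    def test_hand_evaluated_two_unit_head(self):
        m = self._model()
        patch = np.random.default_rng(5).uniform(size=(8, 8))
        s = 0.3
        psi = embed(m, patch)
        W1 = np.arange(2 * (m.embed_dim + 1)).reshape(2, -1) * 0.05 - 0.2
        b1 = np.array([0.1, -0.05])
        W2 = np.array([[0.7, -1.1]])
        b2 = np.array([0.2])
        m.fc1.W[...] = W1
        m.fc1.b[...] = b1
        m.fc2.W[...] = W2
        m.fc2.b[...] = b2
        z = np.concatenate([psi, [s]])
        h = np.maximum(W1 @ z + b1, 0.0)
        expected = 1.0 / (1.0 + np.exp(-(W2 @ h + b2)[0]))
        assert adjudicate(m, patch, s) == pytest.approx(expected, abs=1e-12)


class TestFocalLoss:
    def test_gamma_zero_is_cross_entropy_value(self):
        assert focal_loss(np.array([0.5]), np.array([1]), 0.0) == pytest.approx(
            np.log(2)
        )

    def test_gamma_two_modulated_value(self):
        assert focal_loss(np.array([0.5]), np.array([1]), 2.0) == pytest.approx(
            0.25 * np.log(2)
        )

    def test_gamma_zero_equals_bce_on_random_inputs(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, 200)
        y = rng.integers(0, 2, 200)
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert focal_loss(p, y, 0.0) == pytest.approx(bce, abs=1e-10)

    def test_modulating_factor_shrinks_easy_examples(self):
        p, y = np.array([0.99]), np.array([1])
        assert focal_loss(p, y, 2.0) < focal_loss(p, y, 0.0)

    def test_monotone_in_confidence(self):
        grid = np.linspace(0.01, 0.99, 99)
        loss_pos = [focal_loss(np.array([p]), np.array([1]), 2.0) for p in grid]
        loss_neg = [focal_loss(np.array([p]), np.array([0]), 2.0) for p in grid]
        assert all(a > b for a, b in zip(loss_pos, loss_pos[1:]))  # decreasing
        assert all(a < b for a, b in zip(loss_neg, loss_neg[1:]))  # increasing

    def test_extreme_probabilities_clamped(self):
        val = focal_loss(np.array([0.0, 1.0]), np.array([0, 1]), 2.0)
        assert np.isfinite(val)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([0.5]), np.array([1]), -1.0)


class TestGradients:
    def test_full_model_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        m = AdjudicatorModel(patch_size=16, channels=(4, 6), hidden=8, seed=1)
        x = rng.normal(size=(3, 1, 16, 16))
        s = rng.uniform(0, 1, 3)
        y = np.array([1, 0, 1])
        gamma = 2.0
        p = m.forward(x, s)
        m.zero_grad()
        m.backward(focal_loss_grad_logit(p, y, gamma))
        for param, grad in m.params:
            flat, gflat = param.ravel(), grad.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                eps, old = 1e-6, flat[i]
                flat[i] = old + eps
                lp = focal_loss(m.forward(x, s), y, gamma)
                flat[i] = old - eps
                lm = focal_loss(m.forward(x, s), y, gamma)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert gflat[i] == pytest.approx(num, abs=1e-7, rel=1e-5)


def _separable_records(n_per_class: int, patch_size: int = 16, n_patients: int = 8):
    """Bright-square positives vs plain negatives; trivially learnable."""
    from dataclasses import replace

    rng = np.random.default_rng(0)
    records = []
    for i in range(2 * n_per_class):
        y = i % 2
        patch = rng.normal(0.0, 0.05, size=(patch_size, patch_size))
        if y:
            patch[4:12, 4:12] += 2.0
        base = make_record(
            patient_id=f"P{i % n_patients:04d}", y=y, s=0.5,
            box=Box(i + 1, 0, i + 17, 16), image_id=f"img{i}",
        )
        records.append(replace(base, patch=patch))
    return records


class TestTraining:
    def _train_val(self):
        records = _separable_records(40)
        train_r = [r for r in records if int(r.patient_id[1:]) < 6]
        val_r = [r for r in records if int(r.patient_id[1:]) >= 6]
        return train_r, val_r

    def test_separable_fixture_reaches_perfect_validation_f1(self):
        train_r, val_r = self._train_val()
        model = AdjudicatorModel(patch_size=16, channels=(4, 8), hidden=16, seed=0)
        cfg = TrainConfig(max_epochs=2, learning_rate=5e-3, seed=0)
        model, history = train(model, train_r, val_r, cfg)
        assert max(history.val_f1) == 1.0

    def test_frozen_model_stops_after_patience(self):
        train_r, val_r = self._train_val()
        model = AdjudicatorModel(patch_size=16, channels=(4,), hidden=4, seed=0)
        # lr ~ 0: validation F1 can never improve after the first epoch
        cfg = TrainConfig(max_epochs=10, learning_rate=1e-12, patience=1, seed=0)
        _, history = train(model, train_r, val_r, cfg)
        assert len(history.epochs) == 2

    def test_noop_hook_keeps_pool_sizes_constant(self):
        train_r, val_r = self._train_val()
        model = AdjudicatorModel(patch_size=16, channels=(4,), hidden=4, seed=0)
        cfg = TrainConfig(max_epochs=3, learning_rate=1e-3, seed=0)
        _, history = train(
            model, train_r, val_r, cfg, mining_hook=lambda m, e, p: p
        )
        assert len(set(history.n_pos)) == 1
        assert len(set(history.n_neg0)) == 1
        assert set(history.n_hard) == {0}

    def test_best_epoch_restoration(self):
        train_r, val_r = self._train_val()
        model = AdjudicatorModel(patch_size=16, channels=(4, 8), hidden=16, seed=3)
        cfg = TrainConfig(max_epochs=4, learning_rate=5e-3, seed=3)
        model, history = train(model, train_r, val_r, cfg)
        y_val = np.array([r.y for r in val_r])
        from roiadj.metrics import f1_score

        restored_f1 = f1_score(y_val, predict_proba(model, val_r) >= 0.5)
        assert restored_f1 == pytest.approx(max(history.val_f1))
        assert history.selected_epoch == int(np.argmax(history.val_f1))

    def test_reproducible_given_seed(self):
        train_r, val_r = self._train_val()
        histories = []
        for _ in range(2):
            model = AdjudicatorModel(patch_size=16, channels=(4,), hidden=8, seed=1)
            cfg = TrainConfig(max_epochs=2, learning_rate=1e-3, seed=1)
            _, h = train(model, train_r, val_r, cfg)
            histories.append((h.train_loss, h.val_f1))
        assert histories[0] == histories[1]

    def test_empty_training_set_rejected(self):
        _, val_r = self._train_val()
        model = AdjudicatorModel(patch_size=16, channels=(4,), seed=0)
        with pytest.raises(ValueError):
            train(model, [], val_r, TrainConfig())

    def test_patient_overlap_between_train_and_val_rejected(self):
        train_r, _ = self._train_val()
        model = AdjudicatorModel(patch_size=16, channels=(4,), seed=0)
        with pytest.raises(ValueError):
            train(model, train_r, train_r[:4], TrainConfig(max_epochs=1))
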