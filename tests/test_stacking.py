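"""Softmax scale weights, ensemble prediction, stacking fit, weight report."""

import itertools

import numpy as np
import pytest

from scalestack.classifiers import ProbTensor
from scalestack.nn import sigmoid
from scalestack.stacking import (StackingParams, ensemble_predict,
                                 softmax_weights, train_stacking,
                                 weight_report)


def _prob_tensor(logits):
    logits = np.asarray(logits, dtype=np.float64)
    n, f, s = logits.shape
    return ProbTensor([f"i{k}" for k in range(n)],
                      [f"f{k}" for k in range(f)],
                      list(range(s)), logits)


class TestSoftmaxWeights:
    def test_zero_matrix_gives_uniform_rows(self):
        W = softmax_weights(np.zeros((3, 4)))
        assert np.allclose(W, 0.25)

    def test_ln2_row_closed_form(self):
        W = softmax_weights(np.array([[np.log(2), 0.0, 0.0, 0.0]]))
        assert np.allclose(W, [[0.4, 0.2, 0.2, 0.2]], atol=1e-15)

    def test_rows_sum_to_one_for_random_matrices(self, rng):
        for _ in range(1000):
            V = rng.normal(0, 10, size=(4, 4))
            assert np.allclose(softmax_weights(V).sum(axis=1), 1.0, atol=1e-12)

    def test_stable_under_large_magnitudes(self):
        W = softmax_weights(np.array([[1e4, 1e4 - 1.0]]))
        assert np.isfinite(W).all()
        assert W.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            softmax_weights(np.array([[np.inf, 0.0]]))


class TestEnsemblePredict:
    def test_identical_probabilities_fixed_point(self, rng):
        logit = 0.7
        probs = _prob_tensor(np.full((5, 2, 4), logit))
        W = softmax_weights(rng.normal(size=(2, 4)))
        out = ensemble_predict(W, probs)
        assert np.allclose(out, sigmoid(np.float64(logit)))

    def test_one_hot_row_selects_single_scale(self):
        logits = np.arange(24, dtype=float).reshape(2, 3, 4) / 10
        probs = _prob_tensor(logits)
        W = np.zeros((3, 4))
        W[:, 2] = 1.0
        out = ensemble_predict(W, probs)
        assert np.allclose(out, sigmoid(logits[:, :, 2]))

    def test_uniform_weights_average_probabilities(self):
        p = np.array([0.8, 0.6, 0.4, 0.2])
        logits = np.log(p / (1 - p))[None, None, :]
        out = ensemble_predict(np.full((1, 4), 0.25), _prob_tensor(logits))
        assert out[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        probs = _prob_tensor(np.zeros((2, 3, 4)))
        with pytest.raises(ValueError):
            ensemble_predict(np.full((2, 4), 0.25), probs)


class TestTrainStacking:
    def test_identical_scales_keep_uniform_weights(self, rng):
        base = rng.normal(size=(50, 2, 1))
        logits = np.repeat(base, 4, axis=2)
        labels = (rng.random((50, 2)) < 0.5).astype(int)
        params, _ = train_stacking(_prob_tensor(logits), labels)
        assert np.allclose(params.W, 0.25, atol=1e-12)

    def test_signal_scale_wins_and_matches_simplex_grid_oracle(self, rng):
        """When only one scale carries signal, the learned weight concentrates
        there, in agreement with a brute-force grid search on the simplex."""
        n, s_signal = 400, 1
        y = (rng.random(n) < 0.5).astype(int)
        logits = rng.normal(0, 1, size=(n, 1, 3))
        logits[:, 0, s_signal] = 3.0 * (2 * y - 1) + 0.5 * rng.normal(size=n)
        probs = _prob_tensor(logits)
        params, _ = train_stacking(probs, y[:, None])
        assert params.W[0, s_signal] > 0.5

        p = probs.probabilities[:, 0, :]
        best, best_w = np.inf, None
        grid = np.linspace(0, 1, 21)
        for w0, w1 in itertools.product(grid, grid):
            if w0 + w1 > 1 + 1e-12:
                continue
            w = np.array([w0, w1, 1 - w0 - w1])
            ens = np.clip(p @ w, 1e-12, 1 - 1e-12)
            bce = -np.mean(y * np.log(ens) + (1 - y) * np.log(1 - ens))
            if bce < best:
                best, best_w = bce, w
        assert int(np.argmax(best_w)) == s_signal

    def test_training_does_not_worsen_uniform_bce(self, rng):
        logits = rng.normal(0, 2, size=(120, 3, 4))
        labels = (rng.random((120, 3)) < 0.4).astype(int)
        probs = _prob_tensor(logits)
        params, log = train_stacking(probs, labels)
        uniform = ensemble_predict(np.full((3, 4), 0.25), probs)
        final = ensemble_predict(params.W, probs)
        eps = 1e-12

        def bce(p):
            return -np.mean(labels * np.log(p + eps) + (1 - labels) * np.log(1 - p + eps))

        assert bce(final) <= bce(uniform) + 1e-12
        assert log["bce"].iloc[-1] <= log["bce"].iloc[0] + 1e-12

    def test_label_shape_mismatch_rejected(self, rng):
        probs = _prob_tensor(rng.normal(size=(10, 2, 3)))
        with pytest.raises(ValueError):
            train_stacking(probs, np.zeros((9, 2)))

    def test_deterministic(self, rng):
        logits = rng.normal(size=(30, 2, 4))
        labels = (rng.random((30, 2)) < 0.5).astype(int)
        a, _ = train_stacking(_prob_tensor(logits), labels)
        b, _ = train_stacking(_prob_tensor(logits), labels)
        assert np.array_equal(a.V, b.V)


class TestWeightReport:
    def test_one_hot_row(self):
        table = weight_report(np.array([[1.0, 0.0, 0.0, 0.0]]))
        row = table.iloc[0, 1:].astype(float).to_numpy()
        assert row.tolist() == [100.0, 0.0, 0.0, 0.0]

    def test_uniform_row(self):
        table = weight_report(np.full((1, 4), 0.25))
        assert table.iloc[0, 1:].astype(float).tolist() == [25.0] * 4

    def test_largest_remainder_preserves_total(self):
        table = weight_report(np.array([[0.327, 0.3, 0.2, 0.173]]))
        row = table.iloc[0, 1:].astype(float).to_numpy()
        assert row.sum() == pytest.approx(100.0, abs=1e-12)

    def test_random_rows_always_total_100(self, rng):
        for _ in range(200):
            W = softmax_weights(rng.normal(0, 3, size=(3, 5)))
            table = weight_report(W)
            sums = table.iloc[:, 1:].astype(float).sum(axis=1)
            assert np.allclose(sums, 100.0, atol=1e-12)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            weight_report(np.array([[0.5, 0.6]]))


def test_stacking_params_w_rederived_from_v():
    params = StackingParams(V=np.array([[1.0, -1.0]]), findings=["f"], scales=[32, 64])
    params.V[0, 0] = 5.0
    assert np.allclose(params.W, softmax_weights(np.array([[5.0, -1.0]])))
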