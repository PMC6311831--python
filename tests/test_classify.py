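"""Classifier: forward pass, LM optimizer behavior, evaluation bookkeeping."""

import numpy as np
import pytest
from scipy import special

from macuseg import (
    NetworkParams,
    TrainConfig,
    evaluate,
    predict,
    sample_feature_vectors,
    standardize,
    train_network,
)
from macuseg.classify import (
    LAYER_SIZES,
    _pack,
    _residuals_and_jacobian,
    _train_lm,
    forward,
    init_params,
    stratified_split,
)


class TestStandardize:
    def test_train_statistics_are_zero_mean_unit_sd(self, rng):
        x = rng.normal(5, 3, (40, 11))
        z, _, _ = standardize(x, x)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1, atol=1e-12)

    def test_constant_feature_centered_not_scaled(self, rng):
        x = rng.normal(0, 1, (10, 11))
        x[:, 3] = 7.0
        z, _, _ = standardize(x, x)
        assert np.allclose(z[:, 3], 0.0)

    def test_test_transform_uses_train_statistics_only(self, rng):
        train = rng.normal(0, 1, (20, 11))
        test = rng.normal(10, 5, (20, 11))
        z, mean, std = standardize(train, test)
        assert np.allclose(z, (test - train.mean(0)) / train.std(0))


class TestForwardPass:
    def test_zero_network_outputs_one_half_everywhere(self):
        params = NetworkParams(
            weights=[np.zeros((o, i)) for i, o in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:])],
            biases=[np.zeros(o) for o in LAYER_SIZES[1:]],
        )
        idx, y = predict(params, np.ones(11))
        assert np.allclose(y, 0.5)
        assert idx[0] == 0  # argmax tie broken toward lowest class index

    def test_matches_hand_coded_matrix_chain(self, rng):
        params = init_params(rng)
        x = rng.normal(0, 1, (5, 11))
        y = forward(params, x)
        w1, w2, w3 = params.weights
        b1, b2, b3 = params.biases
        for i in range(5):
            a1 = np.tanh(w1 @ x[i] + b1)
            a2 = np.tanh(w2 @ a1 + b2)
            expected = special.expit(w3 @ a2 + b3)
            assert np.allclose(y[i], expected, atol=1e-12)

    def test_jacobian_matches_finite_differences(self, rng):
        x = rng.normal(0, 1, (3, 11))
        t = np.eye(4)[[0, 1, 2]]
        theta = _pack(init_params(rng))
        r, jac = _residuals_and_jacobian(theta, x, t)
        eps = 1e-6
        for col in rng.choice(theta.size, 15, replace=False):
            bump = theta.copy()
            bump[col] += eps
            r2, _ = _residuals_and_jacobian(bump, x, t)
            assert np.allclose((r2 - r) / eps, jac[:, col], atol=1e-4)

    def test_wrong_length_rejected(self, rng):
        with pytest.raises(ValueError):
            forward(init_params(rng), np.ones(7))


class TestLevenbergMarquardt:
    def test_loss_non_increasing_across_accepted_steps(self, rng):
        x, labels = sample_feature_vectors(4, seed=3)
        z, *_ = standardize(x, x)
        t = np.eye(4)[labels]
        theta0 = _pack(init_params(rng))
        r0, _ = _residuals_and_jacobian(theta0, z, t)
        theta, sse = _train_lm(z, t, theta0, TrainConfig(max_epochs=30))
        assert sse <= float(r0 @ r0)

    def test_limits_gauss_newton_and_gradient_descent(self, rng):
        """λ→0 gives the Gauss–Newton step; λ→∞ a scaled gradient step."""
        x = rng.normal(0, 1, (6, 11))
        t = np.eye(4)[rng.integers(0, 4, 6)]
        theta = _pack(init_params(rng))
        r, jac = _residuals_and_jacobian(theta, x, t)
        grad = jac.T @ r
        hess = jac.T @ jac
        eye = np.eye(theta.size)
        gn = np.linalg.solve(hess + 1e-12 * eye, -grad)
        small_lam = np.linalg.solve(hess + 1e-9 * eye, -grad)
        # J'J of a random net is ill-conditioned; compare step vectors
        # as a whole rather than tiny individual components
        assert np.linalg.norm(small_lam - gn) < 1e-2 * np.linalg.norm(gn)
        lam = 1e9
        grad_step = np.linalg.solve(hess + lam * eye, -grad)
        cos = grad_step @ (-grad) / (
            np.linalg.norm(grad_step) * np.linalg.norm(grad)
        )
        assert cos > 0.9999

    def test_separable_clusters_reach_perfect_accuracy(self, rng):
        centers = rng.normal(0, 10, (4, 11))
        x = np.vstack([centers[c] + rng.normal(0, 1e-3, (10, 11)) for c in range(4)])
        labels = np.repeat(np.arange(4), 10)
        _params, report = train_network(x, labels, TrainConfig(seed=1))
        assert report.accuracy == 100.0

    def test_petechiae_never_confused_with_trophic(self):
        """True petechiae are never predicted trophic: their areas sit
        hundreds of petechiae SDs below the trophic distribution.  (The
        reverse direction is not certain: the wide trophic area SD lets
        individual trophic draws land near petechiae scale.)"""
        for seed in range(5):
            x, labels = sample_feature_vectors(10, seed=seed)
            _params, report = train_network(x, labels, TrainConfig(seed=seed))
            assert report.confusion[1, 2] == 0  # petechiae -> trophic

    def test_non_finite_features_rejected(self):
        x, labels = sample_feature_vectors(3, seed=0)
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_network(x, labels)

    def test_bfgs_fallback_trains_behind_same_interface(self):
        x, labels = sample_feature_vectors(4, seed=2)
        _params, report = train_network(
            x, labels, TrainConfig(seed=2, optimizer="bfgs", max_epochs=150)
        )
        assert 0.0 <= report.accuracy <= 100.0


class TestEvaluate:
    def test_perfect_saturated_predictions(self):
        params = _perfect_lookup_params()
        x = np.eye(4)[[0, 1, 2, 3]] @ np.eye(4, 11) * 10
        labels = np.arange(4)
        report = evaluate(params, x, labels)
        assert report.accuracy == 100.0
        assert report.regression_r > 0.99

    def test_constant_outputs_have_zero_regression_r(self):
        params = NetworkParams(
            weights=[np.zeros((o, i)) for i, o in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:])],
            biases=[np.zeros(o) for o in LAYER_SIZES[1:]],
        )
        x = np.zeros((8, 11))
        labels = np.repeat(np.arange(4), 2)
        report = evaluate(params, x, labels)
        assert report.regression_r == 0.0

    def test_confusion_rows_sum_to_class_counts(self, rng):
        x, labels = sample_feature_vectors(6, seed=5)
        params, _ = train_network(x, labels, TrainConfig(seed=5))
        report = evaluate(params, x, labels)
        assert report.confusion.sum() == labels.size
        assert np.array_equal(report.confusion.sum(axis=1), np.bincount(labels))

    def test_empty_test_set_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluate(init_params(rng), np.empty((0, 11)), np.empty(0, int))


class TestSplit:
    def test_stratified_60_40(self, rng):
        labels = np.repeat(np.arange(4), 10)
        train, test = stratified_split(labels, 0.6, rng)
        assert len(train) == 24 and len(test) == 16
        assert np.array_equal(np.bincount(labels[train]), [6] * 4)
        assert not set(train) & set(test)

    def test_model_serialization_round_trip(self, rng):
        x, labels = sample_feature_vectors(3, seed=9)
        params, _ = train_network(x, labels, TrainConfig(seed=9, max_epochs=20))
        clone = NetworkParams.from_dict(params.to_dict())
        p1, y1 = predict(params, x)
        p2, y2 = predict(clone, x)
        assert np.array_equal(p1, p2)
        assert np.allclose(y1, y2)


def _perfect_lookup_params():
    """Hand-built net whose outputs saturate to the first 4 input dims."""
    w1 = np.zeros((4, 11))
    w1[:4, :4] = np.eye(4) * 50
    w2 = np.eye(4) * 50
    w3 = np.eye(4) * 50
    return NetworkParams(
        weights=[w1, w2, w3],
        biases=[np.zeros(4), np.full(4, -25.0), np.full(4, -25.0)],
    )
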