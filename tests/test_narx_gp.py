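"""Static and NARX design construction, training and OSA prediction."""

import numpy as np
import pytest

from kneegp import (
    GPTrainConfig,
    GPHyperparameters,
    LagSpec,
    build_narx_design,
    build_static_design,
    predict_osa,
    predict_static,
    train_narx_from_segments,
    train_predictor,
    train_static_from_segments,
)
from kneegp.errors import DegenerateDataError, InvalidInputError, StateError

FAST = GPTrainConfig(n_restarts=1, maxiter=60)


class TestStaticDesign:
    def test_rows_in_original_order(self):
        a = np.array([[0.1, 0.9], [0.2, 0.8], [0.3, 0.7]])
        X, idx = build_static_design(a)
        np.testing.assert_array_equal(X, a)
        np.testing.assert_array_equal(idx, [0, 1, 2])

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(InvalidInputError):
            build_static_design(np.zeros((5, 3)))


class TestNarxDesign:
    def test_column_count_second_order_two_channels(self):
        """n_u = n_y = 2 with 2 channels: 2*3 input + 2 output = 8 columns."""
        a = np.random.default_rng(0).uniform(0, 1, size=(10, 2))
        y = np.arange(10.0)
        X, targets, idx = build_narx_design(a, y, LagSpec(2, 2))
        assert X.shape == (8, 8)
        assert targets.shape == (8,)

    def test_warmup_row_arithmetic(self):
        a = np.zeros((10, 2))
        X, _, idx = build_narx_design(a, np.arange(10.0), LagSpec(2, 2))
        assert len(idx) == 8 and idx[0] == 2 and idx[-1] == 9

    def test_row_bookkeeping_on_integer_sequence(self):
        """Row for k reproduces direct slices of the (u, y) series."""
        n = 8
        a = np.column_stack([np.arange(n, dtype=float), 10 + np.arange(n, dtype=float)])
        y = 100.0 + np.arange(n)
        lags = LagSpec(2, 2)
        X, targets, idx = build_narx_design(a, y, lags)
        for row, k in zip(X, idx):
            expected = np.concatenate(
                [a[k], a[k - 1], a[k - 2], [y[k - 1], y[k - 2]]]
            )
            np.testing.assert_array_equal(row, expected)
            assert targets[list(idx).index(k)] == y[k]

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidInputError):
            build_narx_design(np.zeros((3, 2)), np.zeros(3), LagSpec(2, 2))


def _toy_system(n, rng, noise=0.0):
    """y_k = 0.5 y_{k-1} + u_k: linear, inside the NARX-GP model class."""
    u = rng.uniform(0, 1, size=(n, 2))
    y = np.zeros(n)
    for k in range(1, n):
        y[k] = 0.5 * y[k - 1] + u[k, 0] + noise * rng.standard_normal()
    return u, y


class TestTraining:
    def test_training_is_deterministic(self, rng):
        u, y = _toy_system(80, rng)
        p1 = train_narx_from_segments([(u, y)], LagSpec(2, 2), config=FAST, seed=3)
        p2 = train_narx_from_segments([(u, y)], LagSpec(2, 2), config=FAST, seed=3)
        np.testing.assert_array_equal(p1.model.alpha_vec, p2.model.alpha_vec)
        assert p1.model.theta == p2.model.theta

    def test_denormalization_round_trip(self, rng):
        u, y = _toy_system(60, rng)
        p = train_narx_from_segments([(u, y)], LagSpec(2, 2), config=FAST, seed=0)
        np.testing.assert_allclose(p.denormalize(p.normalize(y)), y, atol=1e-12)

    def test_constant_targets_rejected(self):
        with pytest.raises(DegenerateDataError):
            train_predictor(np.random.default_rng(0).uniform(size=(20, 2)),
                            np.full(20, 5.0))

    def test_mode_contract_enforced(self, rng):
        u, y = _toy_system(60, rng)
        static = train_static_from_segments([(u, y)], config=FAST, seed=0)
        narx = train_narx_from_segments([(u, y)], LagSpec(2, 2), config=FAST, seed=0)
        with pytest.raises(StateError):
            predict_osa(static, u, y)
        with pytest.raises(StateError):
            predict_static(narx, u)


class TestPrediction:
    def test_osa_on_noiseless_toy_system_is_near_exact(self, rng):
        """Held-out OSA NRMSE < 0.01 when the system is in the model class."""
        from kneegp import nrmse

        u_tr, y_tr = _toy_system(300, rng)
        u_te, y_te = _toy_system(120, rng)
        p = train_narx_from_segments([(u_tr, y_tr)], LagSpec(2, 2),
                                     config=GPTrainConfig(n_restarts=2, maxiter=200),
                                     seed=1)
        res = predict_osa(p, u_te, y_te)
        assert nrmse(res.y_hat, y_te[res.k_index]) < 0.01

    def test_band_is_exactly_two_sd(self, rng):
        u, y = _toy_system(100, rng)
        p = train_narx_from_segments([(u, y)], LagSpec(2, 2), config=FAST, seed=0)
        res = predict_osa(p, u, y)
        np.testing.assert_allclose(res.ci_high - res.y_hat, 2 * res.sd, atol=1e-12)
        np.testing.assert_allclose(res.y_hat - res.ci_low, 2 * res.sd, atol=1e-12)
        assert np.all(res.ci_low <= res.y_hat) and np.all(res.y_hat <= res.ci_high)

    def test_osa_uses_only_past_outputs(self, rng):
        """Perturbing y_j for j >= k never changes the prediction at k."""
        u, y = _toy_system(100, rng)
        p = train_narx_from_segments([(u, y)], LagSpec(2, 2), config=FAST, seed=0)
        base = predict_osa(p, u, y)
        k_probe = 50
        y_pert = y.copy()
        y_pert[k_probe:] += 5.0
        pert = predict_osa(p, u, y_pert)
        i = list(base.k_index).index(k_probe)
        assert pert.y_hat[i] == base.y_hat[i]

    def test_static_prediction_deterministic_and_reverts_to_prior(self, rng):
        u, y = _toy_system(120, rng)
        p = train_static_from_segments([(u, y)], config=FAST, seed=0)
        r1, r2 = predict_static(p, u), predict_static(p, u)
        np.testing.assert_array_equal(r1.y_hat, r2.y_hat)
        far = np.full((1, 2), 50.0)  # far outside [0, 1] training range
        res = predict_static(p, far)
        prior_mean_deg = p.denormalize(np.array([p.model.mean_const]))[0]
        assert res.y_hat[0] == pytest.approx(prior_mean_deg, abs=1e-6)
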