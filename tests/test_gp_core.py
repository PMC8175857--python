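"""GP core: kernel, posterior, marginal likelihood, gradient, optimizer.

The reference throughout is a naive dense-inverse implementation of the
closed-form posterior and marginal likelihood, kept deliberately separate
from the Cholesky-based production path.
"""

import numpy as np
import pytest

from kneegp import (
    GPHyperparameters,
    fit_gp,
    gp_posterior,
    kernel_matrix,
    log_marginal_likelihood,
    lml_gradient,
    optimize_hyperparameters,
    se_kernel,
)
from kneegp.errors import ConditioningError, InvalidInputError


def dense_posterior(X, Y, Xs, theta):
    """Brute-force posterior via explicit matrix inverse (oracle)."""
    K = kernel_matrix(X, X, theta) + theta.sigma_n**2 * np.eye(len(X))
    Ks = kernel_matrix(Xs, X, theta)
    Kss = kernel_matrix(Xs, Xs, theta)
    K_inv = np.linalg.inv(K)
    m = Y.mean()
    mu = Ks @ K_inv @ (Y - m) + m
    cov = Kss - Ks @ K_inv @ Ks.T
    return mu, cov


def dense_lml(X, Y, theta):
    K = kernel_matrix(X, X, theta) + theta.sigma_n**2 * np.eye(len(X))
    r = Y - Y.mean()
    return (
        -0.5 * r @ np.linalg.inv(K) @ r
        - 0.5 * np.linalg.slogdet(K)[1]
        - 0.5 * len(Y) * np.log(2 * np.pi)
    )


class TestSEKernel:
    def test_zero_distance_gives_signal_variance(self):
        th = GPHyperparameters(2.0, 1.0, 0.0)
        assert se_kernel([1.0, 2.0], [1.0, 2.0], th) == pytest.approx(4.0)

    def test_unit_hypers_at_squared_distance_two(self):
        th = GPHyperparameters(1.0, 1.0, 0.0)
        x, xp = np.zeros(2), np.array([1.0, 1.0])  # ||x - x'||^2 = 2
        assert se_kernel(x, xp, th) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_monotone_decay_with_distance(self):
        th = GPHyperparameters(1.0, 0.7, 0.0)
        vals = [se_kernel([0.0], [d], th) for d in np.linspace(0, 10, 25)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-8

    def test_dimension_mismatch_rejected(self):
        th = GPHyperparameters(1.0, 1.0, 0.0)
        with pytest.raises(InvalidInputError):
            se_kernel([1.0], [1.0, 2.0], th)


class TestKernelMatrix:
    def test_single_point_matrix(self):
        th = GPHyperparameters(1.5, 1.0, 0.0)
        K = kernel_matrix(np.array([[0.3]]), np.array([[0.3]]), th)
        assert K.shape == (1, 1) and K[0, 0] == pytest.approx(1.5**2)

    def test_symmetry_and_psd(self, rng):
        th = GPHyperparameters(1.0, 0.8, 0.0)
        X = rng.normal(size=(6, 2))
        K = kernel_matrix(X, X, th)
        assert np.array_equal(K, K.T)
        assert np.all(np.linalg.eigvalsh(K + 1e-6 * np.eye(6)) > 0)


class TestFitAndPosterior:
    def test_alpha_matches_hand_2x2_solve(self):
        th = GPHyperparameters(1.0, 1.0, 0.5)
        X = np.array([[0.0], [1.0]])
        Y = np.array([1.0, 3.0])
        model = fit_gp(X, Y, th)
        K = np.array([[1.25, np.exp(-0.5)], [np.exp(-0.5), 1.25]])
        expected = np.linalg.solve(K, Y - Y.mean())
        np.testing.assert_allclose(model.alpha_vec, expected, rtol=1e-12)
        # cached factor reconstructs K_Y
        np.testing.assert_allclose(
            model.chol_factor @ model.chol_factor.T, K, rtol=1e-10
        )

    def test_refit_is_deterministic(self, rng):
        th = GPHyperparameters(1.0, 1.0, 0.1)
        X, Y = rng.normal(size=(10, 2)), rng.normal(size=10)
        m1, m2 = fit_gp(X, Y, th), fit_gp(X, Y, th)
        np.testing.assert_array_equal(m1.alpha_vec, m2.alpha_vec)
        np.testing.assert_array_equal(m1.chol_factor, m2.chol_factor)

    def test_duplicate_inputs_noise_free_raises_conditioning_error(self):
        th = GPHyperparameters(1.0, 1.0, 0.0)
        X = np.array([[0.5], [0.5], [1.0]])
        with pytest.raises(ConditioningError):
            fit_gp(X, np.array([1.0, 2.0, 3.0]), th)

    def test_near_noise_free_interpolation(self, rng):
        th = GPHyperparameters(1.0, 1.0, 1e-6)
        X = rng.uniform(0, 3, size=(8, 1))
        Y = np.sin(X[:, 0])
        model = fit_gp(X, Y, th)
        post = gp_posterior(model, X)
        np.testing.assert_allclose(post.mu_star, Y, atol=1e-6)

    def test_prior_reversion_far_from_data(self, rng):
        th = GPHyperparameters(1.3, 0.5, 0.1)
        X = rng.uniform(0, 1, size=(12, 1))
        Y = rng.normal(size=12)
        model = fit_gp(X, Y, th)
        post = gp_posterior(model, np.array([[100.0]]))
        assert post.mu_star[0] == pytest.approx(model.mean_const, abs=1e-6)
        assert post.var_star[0] == pytest.approx(th.sigma_f**2, abs=1e-6)

    def test_matches_dense_oracle(self, rng):
        th = GPHyperparameters(1.2, 0.9, 0.3)
        X = rng.normal(size=(9, 3))
        Y = rng.normal(size=9)
        Xs = rng.normal(size=(5, 3))
        model = fit_gp(X, Y, th)
        post = gp_posterior(model, Xs, full_cov=True)
        mu, cov = dense_posterior(X, Y, Xs, th)
        np.testing.assert_allclose(post.mu_star, mu, atol=1e-10)
        np.testing.assert_allclose(post.cov_star, cov, atol=1e-10)
        np.testing.assert_allclose(post.var_star, np.diag(cov), atol=1e-10)

    def test_adding_a_training_point_never_raises_variance(self, rng):
        """Conditioning on more data can only shrink posterior variance."""
        th = GPHyperparameters(1.0, 1.0, 0.2)
        X = rng.uniform(0, 5, size=(15, 1))
        Y = rng.normal(size=15)
        Xs = rng.uniform(0, 5, size=(20, 1))
        v_small = gp_posterior(fit_gp(X[:10], Y[:10], th), Xs).var_star
        v_big = gp_posterior(fit_gp(X, Y, th), Xs).var_star
        assert np.all(v_big <= v_small + 1e-10)


class TestMarginalLikelihood:
    def test_scalar_closed_form(self):
        # N=1 is below fit_gp's minimum but the LML formula still applies
        th = GPHyperparameters(1.0, 1.0, 0.5)
        y = 0.7
        v = 1.0 + 0.25  # k(x,x) + sigma_n^2
        expected = -0.5 * y**2 / v - 0.5 * np.log(v) - 0.5 * np.log(2 * np.pi)
        got = log_marginal_likelihood(th, np.array([[0.0]]), np.array([y]), mean_const=0.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_residual_leaves_only_complexity_terms(self, rng):
        th = GPHyperparameters(1.0, 1.0, 0.3)
        X = rng.normal(size=(6, 2))
        Y = np.full(6, 2.5)  # Y == mean -> data-fit term vanishes
        K = kernel_matrix(X, X, th) + th.sigma_n**2 * np.eye(6)
        expected = -0.5 * np.linalg.slogdet(K)[1] - 3 * np.log(2 * np.pi)
        assert log_marginal_likelihood(th, X, Y) == pytest.approx(expected, rel=1e-10)

    def test_matches_dense_oracle_random(self, rng):
        th = GPHyperparameters(0.8, 1.4, 0.25)
        X = rng.normal(size=(8, 2))
        Y = rng.normal(size=8)
        assert log_marginal_likelihood(th, X, Y) == pytest.approx(
            dense_lml(X, Y, th), rel=1e-10
        )

    def test_matches_sklearn_cross_check(self, rng):
        """Independent cross-check against scikit-learn's GP marginal
        likelihood at fixed hyperparameters (zero mean)."""
        sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        th = GPHyperparameters(1.3, 0.7, 0.4)
        X = rng.normal(size=(12, 2))
        Y = rng.normal(size=12)
        kern = ConstantKernel(th.sigma_f**2, "fixed") * RBF(th.sigma_l, "fixed") \
            + WhiteKernel(th.sigma_n**2, "fixed")
        gp = sklearn_gp.GaussianProcessRegressor(kernel=kern, optimizer=None)
        gp.fit(X, Y)
        ours = log_marginal_likelihood(th, X, Y, mean_const=0.0)
        assert ours == pytest.approx(gp.log_marginal_likelihood(), rel=1e-8)


class TestGradient:
    def finite_difference(self, th, X, Y, step=1e-5):
        lv = th.log_vector()
        fd = np.zeros(3)
        for i in range(3):
            e = np.zeros(3)
            e[i] = step
            hi = log_marginal_likelihood(GPHyperparameters.from_log_vector(lv + e), X, Y)
            lo = log_marginal_likelihood(GPHyperparameters.from_log_vector(lv - e), X, Y)
            fd[i] = (hi - lo) / (2 * step)
        return fd

    def test_analytic_matches_finite_differences(self, rng):
        for _ in range(5):
            th = GPHyperparameters(*np.exp(rng.uniform(-1, 1, 3)))
            X = rng.normal(size=(6, 2))
            Y = rng.normal(size=6)
            g = lml_gradient(th, X, Y)
            fd = self.finite_difference(th, X, Y)
            np.testing.assert_allclose(g, fd, rtol=1e-4, atol=1e-7)

    def test_noise_gradient_nonpositive_for_perfect_fit(self):
        """With residual-free data and noise at the floor, increasing the
        noise cannot improve the likelihood."""
        th = GPHyperparameters(1.0, 1.0, 1e-6)
        X = np.linspace(0, 1, 6)[:, None]
        Y = np.full(6, 0.0)
        g = lml_gradient(th, X, Y, mean_const=0.0)
        assert g[2] <= 1e-10


class TestOptimizer:
    def test_result_never_worse_than_init(self, rng):
        X = rng.uniform(0, 5, size=(30, 1))
        Y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(30)
        init = GPHyperparameters(1.0, 1.0, 0.5)
        best = optimize_hyperparameters(X, Y, init, n_restarts=2, seed=0)
        assert log_marginal_likelihood(best, X, Y) >= log_marginal_likelihood(init, X, Y) - 1e-9

    def test_fixed_point_returns_near_init(self, rng):
        """Starting at an optimum, one more optimization stays there."""
        X = rng.uniform(0, 5, size=(40, 1))
        Y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(40)
        init = GPHyperparameters(1.0, 1.0, 0.3)
        opt = optimize_hyperparameters(X, Y, init, n_restarts=1, seed=0)
        again = optimize_hyperparameters(X, Y, opt, n_restarts=1, seed=0)
        assert log_marginal_likelihood(again, X, Y) == pytest.approx(
            log_marginal_likelihood(opt, X, Y), abs=1e-4
        )
        g = lml_gradient(opt, X, Y)
        assert np.linalg.norm(g) < 1e-3
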