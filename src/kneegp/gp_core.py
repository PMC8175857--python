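"""Exact Gaussian-process regression with a squared-exponential kernel.

Everything is written against the standard function-space formulation: a GP
prior ``f ~ GP(m, k)`` with constant mean, observations ``y = f(x) + eps``
with ``eps ~ N(0, sigma_n^2)``, and the closed-form posterior

    mu*    = K(X*, X) [K(X, X) + sigma_n^2 I]^-1 (y - m) + m
    Sigma* = K(X*, X*) - K(X*, X) [K(X, X) + sigma_n^2 I]^-1 K(X, X*)

Hyperparameters theta = (sigma_f, sigma_l, sigma_n) are point-estimated by
maximizing the log marginal likelihood in log space with its analytic
gradient.  All linear algebra goes through a cached Cholesky factor; the
noisy covariance is never inverted explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.spatial.distance import cdist

from .errors import ConditioningError, InvalidInputError, StateError

__all__ = [
    "GPHyperparameters",
    "GPModel",
    "PosteriorResult",
    "se_kernel",
    "kernel_matrix",
    "fit_gp",
    "gp_posterior",
    "log_marginal_likelihood",
    "lml_gradient",
    "optimize_hyperparameters",
]

#: Smallest admissible noise standard deviation during optimization.
SIGMA_N_FLOOR = 1e-6

#: Diagonal jitter ladder tried in order when a Cholesky factorization fails.
JITTER_LADDER = (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6)


@dataclass(frozen=True)
class GPHyperparameters:
    """SE-kernel hyperparameters: signal std, length scale, noise std.

    Stored on the natural scale; optimization happens on ``log`` of each.
    """

    sigma_f: float
    sigma_l: float
    sigma_n: float

    def __post_init__(self) -> None:
        if not (self.sigma_f > 0 and self.sigma_l > 0):
            raise InvalidInputError("sigma_f and sigma_l must be strictly positive")
        if self.sigma_n < 0:
            raise InvalidInputError("sigma_n must be non-negative")

    def log_vector(self) -> np.ndarray:
        return np.log([self.sigma_f, self.sigma_l, max(self.sigma_n, SIGMA_N_FLOOR)])

    @classmethod
    def from_log_vector(cls, v: np.ndarray) -> "GPHyperparameters":
        s = np.exp(np.asarray(v, dtype=float))
        return cls(sigma_f=float(s[0]), sigma_l=float(s[1]), sigma_n=float(s[2]))


@dataclass
class GPModel:
    """A trained GP regressor with cached Cholesky factor and alpha vector.

    ``chol_factor`` is the lower-triangular factor of
    ``K_Y = K(X, X) + sigma_n^2 I (+ jitter)``; ``alpha_vec`` solves
    ``K_Y alpha = Y - mean_const``.
    """

    X_train: np.ndarray
    Y_train: np.ndarray
    mean_const: float
    theta: GPHyperparameters
    chol_factor: np.ndarray
    alpha_vec: np.ndarray
    jitter: float = 0.0


@dataclass
class PosteriorResult:
    """Posterior mean and (diagonal) variance at the prediction inputs."""

    mu_star: np.ndarray
    var_star: np.ndarray
    cov_star: np.ndarray | None = None


def se_kernel(x: np.ndarray, x_prime: np.ndarray, theta: GPHyperparameters) -> float:
    """Squared-exponential covariance between two points:
    ``sigma_f^2 exp(-||x - x'||^2 / (2 sigma_l^2))``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    x_prime = np.atleast_1d(np.asarray(x_prime, dtype=float))
    if x.shape != x_prime.shape:
        raise InvalidInputError(
            f"dimension mismatch: {x.shape} vs {x_prime.shape}"
        )
    sq = float(np.sum((x - x_prime) ** 2))
    return theta.sigma_f**2 * float(np.exp(-sq / (2.0 * theta.sigma_l**2)))


def _as_design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise InvalidInputError("design matrix must be 1- or 2-dimensional")
    return X


def kernel_matrix(
    X: np.ndarray, X2: np.ndarray, theta: GPHyperparameters
) -> np.ndarray:
    """Cross-covariance matrix ``K[i, j] = k(X[i], X2[j])`` under the SE kernel."""
    X = _as_design(X)
    X2 = _as_design(X2)
    if X.shape[1] != X2.shape[1]:
        raise InvalidInputError(
            f"dimension mismatch: d={X.shape[1]} vs d={X2.shape[1]}"
        )
    if X is X2 or (X.shape == X2.shape and np.array_equal(X, X2)):
        sq = cdist(X, X, metric="sqeuclidean")
        sq = 0.5 * (sq + sq.T)  # exact symmetry
    else:
        sq = cdist(X, X2, metric="sqeuclidean")
    return theta.sigma_f**2 * np.exp(-sq / (2.0 * theta.sigma_l**2))


def _chol_with_jitter(K: np.ndarray, sigma_n: float) -> tuple[np.ndarray, float]:
    """Cholesky of ``K + sigma_n^2 I`` with escalating diagonal jitter.

    When ``sigma_n == 0`` no jitter is applied: a noise-free GP requires a
    strictly positive-definite kernel matrix, and masking rank deficiency
    with jitter would silently change the model.
    """
    n = K.shape[0]
    ladder = (0.0,) if sigma_n == 0.0 else JITTER_LADDER
    attempted = []
    for jitter in ladder:
        try:
            L = cholesky(
                K + (sigma_n**2 + jitter) * np.eye(n), lower=True, check_finite=False
            )
            return L, jitter
        except np.linalg.LinAlgError:
            attempted.append(jitter)
        except Exception:  # scipy raises its own LinAlgError subclass
            attempted.append(jitter)
    raise ConditioningError(
        "Cholesky factorization failed; attempted jitter values: "
        + ", ".join(f"{j:g}" for j in attempted)
    )


def fit_gp(X: np.ndarray, Y: np.ndarray, theta: GPHyperparameters) -> GPModel:
    """Fit (condition) a GP on training data at fixed hyperparameters.

    The prior mean is the constant ``mean(Y)``; the Cholesky factor of the
    noisy covariance and ``alpha = K_Y^{-1}(Y - mean)`` are cached for
    posterior evaluation.
    """
    X = _as_design(X)
    Y = np.asarray(Y, dtype=float).ravel()
    if X.shape[0] != Y.shape[0]:
        raise InvalidInputError("X and Y must have the same number of rows")
    if X.shape[0] < 2:
        raise InvalidInputError("need at least 2 training points")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise InvalidInputError("training data contains non-finite values")
    K = kernel_matrix(X, X, theta)
    L, jitter = _chol_with_jitter(K, theta.sigma_n)
    mean_const = float(np.mean(Y))
    alpha = cho_solve((L, True), Y - mean_const, check_finite=False)
    return GPModel(
        X_train=X,
        Y_train=Y,
        mean_const=mean_const,
        theta=theta,
        chol_factor=L,
        alpha_vec=alpha,
        jitter=jitter,
    )


def gp_posterior(
    model: GPModel,
    X_star: np.ndarray,
    full_cov: bool = False,
    include_noise: bool = False,
) -> PosteriorResult:
    """Posterior mean and variance at new inputs via the cached factorization.

    ``include_noise`` adds ``sigma_n^2`` to the diagonal so the result is a
    predictive (observation-level) variance rather than a latent one.
    """
    if model.chol_factor is None or model.alpha_vec is None:
        raise StateError("model has not been fitted")
    X_star = _as_design(X_star)
    if X_star.shape[1] != model.X_train.shape[1]:
        raise InvalidInputError(
            f"dimension mismatch: d={X_star.shape[1]} vs d={model.X_train.shape[1]}"
        )
    Ks = kernel_matrix(X_star, model.X_train, model.theta)  # M x N
    mu = Ks @ model.alpha_vec + model.mean_const
    V = solve_triangular(model.chol_factor, Ks.T, lower=True, check_finite=False)
    var = model.theta.sigma_f**2 - np.sum(V**2, axis=0)
    var = np.maximum(var, 0.0)
    cov = None
    if full_cov:
        Kss = kernel_matrix(X_star, X_star, model.theta)
        cov = Kss - V.T @ V
        if include_noise:
            cov = cov + model.theta.sigma_n**2 * np.eye(X_star.shape[0])
    if include_noise:
        var = var + model.theta.sigma_n**2
    return PosteriorResult(mu_star=mu, var_star=var, cov_star=cov)


def _prepare_lml(
    theta: GPHyperparameters,
    X: np.ndarray,
    Y: np.ndarray,
    mean_const: float | None,
):
    X = _as_design(X)
    Y = np.asarray(Y, dtype=float).ravel()
    if mean_const is None:
        mean_const = float(np.mean(Y))
    K = kernel_matrix(X, X, theta)
    L, _ = _chol_with_jitter(K, theta.sigma_n)
    resid = Y - mean_const
    alpha = cho_solve((L, True), resid, check_finite=False)
    return X, resid, K, L, alpha


def log_marginal_likelihood(
    theta: GPHyperparameters,
    X: np.ndarray,
    Y: np.ndarray,
    mean_const: float | None = None,
) -> float:
    """Log marginal likelihood
    ``-1/2 r^T K_Y^-1 r - 1/2 log|K_Y| - N/2 log 2pi`` with ``r = Y - mean``.

    The log-determinant is accumulated from the triangular factor.
    """
    _, resid, _, L, alpha = _prepare_lml(theta, X, Y, mean_const)
    n = resid.shape[0]
    log_det = 2.0 * float(np.sum(np.log(np.diag(L))))
    return float(
        -0.5 * resid @ alpha - 0.5 * log_det - 0.5 * n * np.log(2.0 * np.pi)
    )


def lml_gradient(
    theta: GPHyperparameters,
    X: np.ndarray,
    Y: np.ndarray,
    mean_const: float | None = None,
) -> np.ndarray:
    """Analytic gradient of the log marginal likelihood w.r.t.
    ``(log sigma_f, log sigma_l, log sigma_n)``.

    Uses the trace identity ``d/dtheta = 1/2 tr((alpha alpha^T - K_Y^-1)
    dK_Y/dtheta)`` with the SE-kernel derivatives chain-ruled to log space.
    """
    X, _, K, L, alpha = _prepare_lml(theta, X, Y, mean_const)
    n = K.shape[0]
    K_inv = cho_solve((L, True), np.eye(n), check_finite=False)
    A = np.outer(alpha, alpha) - K_inv
    sq = cdist(X, X, metric="sqeuclidean")
    # dK_Y / d log sigma_f = 2 K;  d / d log sigma_l = K * (r^2 / sigma_l^2);
    # d / d log sigma_n = 2 sigma_n^2 I
    dK_f = 2.0 * K
    dK_l = K * (sq / theta.sigma_l**2)
    grad_f = 0.5 * float(np.sum(A * dK_f))
    grad_l = 0.5 * float(np.sum(A * dK_l))
    grad_n = 0.5 * float(np.trace(A)) * 2.0 * theta.sigma_n**2
    return np.array([grad_f, grad_l, grad_n])


def optimize_hyperparameters(
    X: np.ndarray,
    Y: np.ndarray,
    init: GPHyperparameters,
    n_restarts: int = 3,
    seed: int | None = None,
    maxiter: int = 200,
    gtol: float = 1e-6,
) -> GPHyperparameters:
    """Point-estimate hyperparameters by maximizing the log marginal
    likelihood with L-BFGS-B in log space.

    ``n_restarts`` runs start from ``init`` and from log-uniform
    perturbations of it (±1 nat per coordinate, drawn from ``seed``); the
    candidate with the highest marginal likelihood wins, and the result is
    never worse than ``init`` itself.
    """
    if n_restarts < 1:
        raise InvalidInputError("n_restarts must be >= 1")
    X = _as_design(X)
    Y = np.asarray(Y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    mean_const = float(np.mean(Y))

    def neg_lml_and_grad(logv: np.ndarray):
        th = GPHyperparameters.from_log_vector(logv)
        try:
            val = log_marginal_likelihood(th, X, Y, mean_const)
            grad = lml_gradient(th, X, Y, mean_const)
        except ConditioningError:
            return np.inf, np.zeros(3)
        return -val, -grad

    bounds = [
        (np.log(1e-6), np.log(1e6)),
        (np.log(1e-6), np.log(1e6)),
        (np.log(SIGMA_N_FLOOR), np.log(1e6)),
    ]
    x0 = np.clip(init.log_vector(), [b[0] for b in bounds], [b[1] for b in bounds])
    starts = [x0]
    for _ in range(n_restarts - 1):
        starts.append(
            np.clip(
                x0 + rng.uniform(-1.0, 1.0, size=3),
                [b[0] for b in bounds],
                [b[1] for b in bounds],
            )
        )

    best_logv = x0
    best_val, _ = neg_lml_and_grad(x0)
    n_failed = 0
    for start in starts:
        try:
            res = optimize.minimize(
                neg_lml_and_grad,
                start,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "gtol": gtol},
            )
        except (ConditioningError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val = res.fun
            best_logv = res.x
    if n_failed == len(starts) and not np.isfinite(best_val):
        raise ConditioningError(
            f"all {len(starts)} optimizer restarts failed to factorize K_Y"
        )
    return GPHyperparameters.from_log_vector(best_logv)
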