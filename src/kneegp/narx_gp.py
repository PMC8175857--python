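"""Static-GP and GP-NARX joint-angle predictors.

The static predictor maps the instantaneous activation pair
``u_k = [a_1k, a_2k]^T`` to the angle ``y_k`` with a plain GP.  The NARX
predictor adds lagged inputs and lagged measured outputs,

    y*_k = f(u_k, u_{k-1}, ..., u_{k-n_u}, y_{k-1}, ..., y_{k-n_y}),

and performs one-step-ahead (OSA) prediction: the output lags in the
regressor are always MEASURED angles, never fed-back predictions.  With
the default second-order lags (n_u = n_y = 2) and two muscles, each
regressor row has 2*(n_u+1) + n_y = 8 columns.

Angles are min-max normalized to [0, 1] with training-set extrema before
GP fitting; predictions and their uncertainty bands are de-normalized back
to degrees.  The reported variance includes the observation-noise term
sigma_n^2, so mu +/- 2 sd is a predictive interval for a new measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activation_dynamics import ActivationSeries
from .errors import DegenerateDataError, InvalidInputError, StateError
from .gp_core import (
    GPHyperparameters,
    GPModel,
    fit_gp,
    gp_posterior,
    optimize_hyperparameters,
)

__all__ = [
    "LagSpec",
    "PredictionResult",
    "AnglePredictor",
    "build_static_design",
    "build_narx_design",
    "train_predictor",
    "predict_static",
    "predict_osa",
]


@dataclass(frozen=True)
class LagSpec:
    """Maximum input and output lags of the NARX regressor."""

    n_u: int = 2
    n_y: int = 2

    def __post_init__(self) -> None:
        if self.n_u < 0:
            raise InvalidInputError("n_u must be >= 0")
        if self.n_y < 1:
            raise InvalidInputError("n_y must be >= 1 in NARX mode")

    @property
    def warmup(self) -> int:
        return max(self.n_u, self.n_y)

    @property
    def n_columns(self) -> int:
        return 2 * (self.n_u + 1) + self.n_y


@dataclass
class PredictionResult:
    """Per-step posterior prediction in degrees with a mu +/- 2 sigma band."""

    y_hat: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    k_index: np.ndarray


@dataclass
class AnglePredictor:
    """Trained GP (static) or GP-NARX (lags is not None) angle predictor."""

    model: GPModel
    lags: LagSpec | None
    y_min: float
    y_max: float

    @property
    def is_narx(self) -> bool:
        return self.lags is not None

    def normalize(self, y_deg: np.ndarray) -> np.ndarray:
        return (np.asarray(y_deg, dtype=float) - self.y_min) / (self.y_max - self.y_min)

    def denormalize(self, y_norm: np.ndarray) -> np.ndarray:
        return np.asarray(y_norm, dtype=float) * (self.y_max - self.y_min) + self.y_min


def _activation_matrix(activation: ActivationSeries | np.ndarray) -> np.ndarray:
    a = activation.a if isinstance(activation, ActivationSeries) else np.asarray(activation, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise InvalidInputError("activation must have exactly 2 channels")
    return a


def build_static_design(activation: ActivationSeries | np.ndarray):
    """Design matrix for the static predictor: row k is ``[a_1k, a_2k]``.

    Returns ``(X, index_map)`` where ``index_map[i]`` is the angle-sample
    index row i targets (here the identity).
    """
    a = _activation_matrix(activation)
    return a.copy(), np.arange(a.shape[0])


def build_narx_design(
    activation: ActivationSeries | np.ndarray,
    y: np.ndarray,
    lags: LagSpec,
):
    """NARX regressor rows from an activation series and MEASURED outputs.

    Row for time k (k = warmup .. n-1) is
    ``[u_k, u_{k-1}, ..., u_{k-n_u}, y_{k-1}, ..., y_{k-n_y}]``
    with each u a 2-vector; the target is ``y_k``.  Returns
    ``(X, targets, index_map)``.
    """
    a = _activation_matrix(activation)
    y = np.asarray(y, dtype=float).ravel()
    n = a.shape[0]
    if y.size != n:
        raise InvalidInputError("activation and output series lengths differ")
    L = lags.warmup
    if n < L + 2:
        raise InvalidInputError(
            f"series of length {n} is too short for warm-up {L} (need >= {L + 2})"
        )
    ks = np.arange(L, n)
    cols = []
    for lag in range(lags.n_u + 1):
        cols.append(a[ks - lag])           # 2 columns each
    for lag in range(1, lags.n_y + 1):
        cols.append(y[ks - lag][:, None])  # 1 column each
    X = np.hstack(cols)
    return X, y[ks], ks


@dataclass(frozen=True)
class GPTrainConfig:
    """Hyperparameter-optimization settings used when training predictors."""

    init: GPHyperparameters = GPHyperparameters(1.0, 1.0, 0.1)
    n_restarts: int = 3
    maxiter: int = 200
    optimize: bool = True


def train_predictor(
    design: np.ndarray,
    targets_deg: np.ndarray,
    lags: LagSpec | None = None,
    config: GPTrainConfig | None = None,
    seed: int | None = None,
) -> AnglePredictor:
    """Fit a GP on (design, min-max-normalized targets) with optimized
    hyperparameters.

    For NARX designs the output-lag columns of ``design`` must already be
    normalized with the same extrema as the targets; use
    :func:`train_narx_from_segments` for the common case.
    """
    targets_deg = np.asarray(targets_deg, dtype=float).ravel()
    y_min, y_max = float(np.min(targets_deg)), float(np.max(targets_deg))
    if y_max - y_min <= 0:
        raise DegenerateDataError("targets are constant; cannot normalize")
    y_norm = (targets_deg - y_min) / (y_max - y_min)
    if config is None:
        config = GPTrainConfig()
    theta = config.init
    if config.optimize:
        theta = optimize_hyperparameters(
            design, y_norm, config.init, n_restarts=config.n_restarts,
            seed=seed, maxiter=config.maxiter,
        )
    model = fit_gp(design, y_norm, theta)
    return AnglePredictor(model=model, lags=lags, y_min=y_min, y_max=y_max)


def train_static_from_segments(
    segments: list[tuple[np.ndarray, np.ndarray]],
    config: GPTrainConfig | None = None,
    seed: int | None = None,
) -> AnglePredictor:
    """Train the static predictor from ``(activation [n x 2], angle_deg)``
    segments (e.g. one per contiguous block of training cycles)."""
    X = np.vstack([build_static_design(a)[0] for a, _ in segments])
    y = np.concatenate([np.asarray(y, dtype=float).ravel() for _, y in segments])
    return train_predictor(X, y, lags=None, config=config, seed=seed)


def train_narx_from_segments(
    segments: list[tuple[np.ndarray, np.ndarray]],
    lags: LagSpec,
    config: GPTrainConfig | None = None,
    seed: int | None = None,
) -> AnglePredictor:
    """Train the NARX predictor from ``(activation, angle_deg)`` segments.

    Angle extrema are taken over all training targets; output-lag columns
    use the same normalization.  Lagged windows never straddle segment
    boundaries: each segment contributes its own rows after warm-up.
    """
    all_y = np.concatenate([np.asarray(y, dtype=float).ravel() for _, y in segments])
    y_min, y_max = float(np.min(all_y)), float(np.max(all_y))
    if y_max - y_min <= 0:
        raise DegenerateDataError("targets are constant; cannot normalize")
    Xs, ts = [], []
    for a, y in segments:
        y_norm = (np.asarray(y, dtype=float).ravel() - y_min) / (y_max - y_min)
        X, t, _ = build_narx_design(a, y_norm, lags)
        Xs.append(X)
        ts.append(t)
    design = np.vstack(Xs)
    targets = np.concatenate(ts)
    if config is None:
        config = GPTrainConfig()
    theta = config.init
    if config.optimize:
        theta = optimize_hyperparameters(
            design, targets, config.init, n_restarts=config.n_restarts,
            seed=seed, maxiter=config.maxiter,
        )
    model = fit_gp(design, targets, theta)
    return AnglePredictor(model=model, lags=lags, y_min=y_min, y_max=y_max)


def _band(predictor: AnglePredictor, post, ks) -> PredictionResult:
    scale = predictor.y_max - predictor.y_min
    mu_deg = predictor.denormalize(post.mu_star)
    sd_deg = np.sqrt(post.var_star) * scale
    return PredictionResult(
        y_hat=mu_deg,
        sd=sd_deg,
        ci_low=mu_deg - 2.0 * sd_deg,
        ci_high=mu_deg + 2.0 * sd_deg,
        k_index=np.asarray(ks),
    )


def predict_static(
    predictor: AnglePredictor, activation: ActivationSeries | np.ndarray
) -> PredictionResult:
    """Pointwise GP posterior at each activation sample, in degrees."""
    if predictor.is_narx:
        raise StateError("NARX-mode predictor cannot make static predictions")
    X, ks = build_static_design(activation)
    post = gp_posterior(predictor.model, X, include_noise=True)
    return _band(predictor, post, ks)


def predict_osa(
    predictor: AnglePredictor,
    activation: ActivationSeries | np.ndarray,
    y_measured_deg: np.ndarray,
) -> PredictionResult:
    """One-step-ahead NARX prediction using measured output lags.

    The regressor at time k uses only information up to k-1 on the output
    side (and the current input u_k); predictions start after the warm-up
    of ``max(n_u, n_y)`` samples.
    """
    if not predictor.is_narx:
        raise StateError("static-mode predictor cannot make OSA predictions")
    y_measured_deg = np.asarray(y_measured_deg, dtype=float).ravel()
    if not np.all(np.isfinite(y_measured_deg)):
        raise InvalidInputError("measured angles required at all lagged positions")
    y_norm = predictor.normalize(y_measured_deg)
    X, _, ks = build_narx_design(activation, y_norm, predictor.lags)
    post = gp_posterior(predictor.model, X, include_noise=True)
    return _band(predictor, post, ks)
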