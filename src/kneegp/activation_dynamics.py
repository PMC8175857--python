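"""Muscle activation dynamics: processed EMG e(t) -> neural activation q(t)
-> muscle activation a(t).

The e->q stage is a second-order discrete recursion with an optional
electromechanical delay,

    q_k = alpha_gain * e_{k-delay} - beta1 * q_{k-1} - beta2 * q_{k-2},

parameterized by its roots gamma1, gamma2 (beta1 = gamma1 + gamma2,
beta2 = gamma1 * gamma2).  Stability requires |gamma| < 1 and unit
steady-state gain requires alpha_gain - beta1 - beta2 = 1, so a constant
envelope c drives q -> c.  The q->a stage is the exponential shaping
nonlinearity

    a(q) = (exp(A q) - 1) / (exp(A) - 1),    A in [-3, 0),

which is monotone with a(0) = 0 and a(1) = 1 and accounts for the
nonlinear EMG-to-activation relationship at low effort levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "ActivationParams",
    "ActivationSeries",
    "neural_activation",
    "muscle_activation",
    "activation_from_envelope",
]


@dataclass(frozen=True)
class ActivationParams:
    """Parameters of the activation recursion and shaping nonlinearity.

    gamma1, gamma2 : recursion roots, each with magnitude < 1 (stability).
    alpha_gain is derived as 1 + beta1 + beta2 so the recursion has unit
    steady-state gain.
    delay_steps : electromechanical delay in samples (at the angle rate).
    A_shape : exponential shape factor, in [-3, 0); -> 0 approaches linear.
    """

    gamma1: float = -0.5
    gamma2: float = -0.5
    delay_steps: int = 0
    A_shape: float = -1.0
    clip: bool = True

    def __post_init__(self) -> None:
        if not (abs(self.gamma1) < 1 and abs(self.gamma2) < 1):
            raise InvalidConfigError(
                "recursion roots must satisfy |gamma| < 1 for stability"
            )
        if self.delay_steps < 0 or int(self.delay_steps) != self.delay_steps:
            raise InvalidConfigError("delay_steps must be a non-negative integer")
        if not (-3.0 <= self.A_shape < 0.0):
            raise InvalidConfigError("A_shape must lie in [-3, 0)")

    @property
    def beta1(self) -> float:
        return self.gamma1 + self.gamma2

    @property
    def beta2(self) -> float:
        return self.gamma1 * self.gamma2

    @property
    def alpha_gain(self) -> float:
        # unit steady-state gain: alpha - beta1 - beta2 = 1
        return 1.0 + self.beta1 + self.beta2


@dataclass
class ActivationSeries:
    """Neural and muscle activation for the two muscles, on the angle grid."""

    q: np.ndarray  # [n x 2]
    a: np.ndarray  # [n x 2], in [0, 1]
    time: np.ndarray


def neural_activation(e: np.ndarray, params: ActivationParams) -> np.ndarray:
    """Run the delayed second-order recursion on a processed-EMG envelope.

    The envelope is treated as 0 before its first sample; the recursion
    state starts at 0.  Output is clipped to [0, 1] when ``params.clip``
    (transients of the stable filter can overshoot slightly).
    """
    e = np.asarray(e, dtype=float).ravel()
    if e.size and (np.min(e) < -1e-12 or np.max(e) > 1.0 + 1e-12):
        raise InvalidInputError("envelope values must lie in [0, 1]")
    if params.delay_steps > 0:
        e = np.concatenate([np.zeros(params.delay_steps), e[: e.size - params.delay_steps]])
    q = lfilter([params.alpha_gain], [1.0, params.beta1, params.beta2], e)
    if params.clip:
        q = np.clip(q, 0.0, 1.0)
    return q


def muscle_activation(q: np.ndarray, A_shape: float) -> np.ndarray:
    """Exponential shaping ``a = (exp(A q) - 1) / (exp(A) - 1)``.

    A_shape = 0 is rejected (the formula is singular there); a linear
    passthrough must be requested explicitly by the caller.
    """
    if A_shape == 0.0:
        raise InvalidConfigError(
            "A_shape = 0 is singular; use a linear passthrough explicitly"
        )
    if not (-3.0 <= A_shape < 0.0):
        raise InvalidConfigError("A_shape must lie in [-3, 0)")
    q = np.asarray(q, dtype=float)
    if q.size and (np.min(q) < -1e-12 or np.max(q) > 1.0 + 1e-12):
        raise InvalidInputError("neural activation must lie in [0, 1]")
    return np.expm1(A_shape * q) / np.expm1(A_shape)


def activation_from_envelope(
    e: np.ndarray, time: np.ndarray, params: ActivationParams | None = None
) -> ActivationSeries:
    """Apply the full e -> q -> a chain to a two-channel envelope matrix."""
    if params is None:
        params = ActivationParams()
    e = np.asarray(e, dtype=float)
    if e.ndim != 2 or e.shape[1] != 2:
        raise InvalidInputError("envelope must be an [n x 2] matrix")
    q = np.column_stack([neural_activation(e[:, j], params) for j in range(2)])
    a = np.column_stack([muscle_activation(q[:, j], params.A_shape) for j in range(2)])
    return ActivationSeries(q=q, a=a, time=np.asarray(time, dtype=float))
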