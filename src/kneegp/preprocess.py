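"""sEMG preprocessing: zero-phase filtering, rectification, envelope
extraction, max-normalization and alignment to the angle sampling grid.

The chain applied to each raw channel is the standard envelope pipeline for
gait EMG: a 4th-order zero-phase Butterworth high-pass at 40 Hz to remove
low-frequency motion artifact (optionally band-limited with an upper
corner), full-wave rectification, a 4th-order zero-phase Butterworth
low-pass whose cutoff is 3.5 divided by the step period, and finally
division by the channel's maximum over all of the subject's trials.  The
normalized envelope is then interpolated onto the angle time grid.

Zero-phase filtering is implemented forward-backward (``sosfiltfilt``); the
stated order is the design order of each pass, so the effective attenuation
order is doubled, matching common practice in the gait literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import DegenerateDataError, InvalidConfigError, InvalidInputError

__all__ = [
    "PreprocessConfig",
    "EnvelopeSeries",
    "highpass_zero_phase",
    "rectify",
    "lowpass_envelope",
    "envelope_from_raw",
    "normalize_and_align",
    "extract_envelopes",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter parameters for the EMG envelope pipeline.

    highpass_cutoff_hz : lower corner removing motion artifact (default 40).
    highpass_upper_hz : optional upper corner turning the high-pass into a
        band-pass; ignored (None) unless it fits below Nyquist.
    envelope_cutoff_scale : the low-pass cutoff is this value divided by the
        step period in seconds (default 3.5).
    order : Butterworth design order per pass (default 4).
    """

    highpass_cutoff_hz: float = 40.0
    highpass_upper_hz: float | None = None
    envelope_cutoff_scale: float = 3.5
    order: int = 4


@dataclass
class EnvelopeSeries:
    """Normalized two-channel EMG envelope e(t) on the angle time grid."""

    e: np.ndarray  # [n_angle_samples x 2], in [0, 1]
    time: np.ndarray
    normalization_max: np.ndarray  # per-channel maximum used for division


def highpass_zero_phase(
    signal: np.ndarray,
    rate: float,
    order: int = 4,
    cutoff: float = 40.0,
    upper_cutoff: float | None = None,
) -> np.ndarray:
    """Zero-phase Butterworth high-pass (or band-pass when ``upper_cutoff``
    is given) applied forward-backward."""
    nyq = rate / 2.0
    if not (0 < cutoff < nyq):
        raise InvalidConfigError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyq} Hz)"
        )
    if upper_cutoff is not None:
        if not (cutoff < upper_cutoff < nyq):
            raise InvalidConfigError(
                f"upper cutoff {upper_cutoff} Hz must lie in (cutoff, Nyquist)"
            )
        sos = butter(order, [cutoff, upper_cutoff], btype="bandpass", fs=rate, output="sos")
    else:
        sos = butter(order, cutoff, btype="highpass", fs=rate, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float))


def rectify(signal: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(signal, dtype=float))


def lowpass_envelope(
    signal: np.ndarray,
    rate: float,
    order: int = 4,
    step_period_s: float = 1.0,
    cutoff_scale: float = 3.5,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass with cutoff ``cutoff_scale /
    step_period_s`` Hz, turning a rectified signal into an envelope."""
    if step_period_s <= 0:
        raise InvalidConfigError("step period must be positive")
    cutoff = cutoff_scale / step_period_s
    nyq = rate / 2.0
    if cutoff >= nyq:
        raise InvalidConfigError(
            f"envelope cutoff {cutoff} Hz must be below Nyquist ({nyq} Hz)"
        )
    sos = butter(order, cutoff, btype="lowpass", fs=rate, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float))


def envelope_from_raw(
    emg: np.ndarray,
    rate: float,
    step_period_s: float,
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    """High-pass, rectify and low-pass each raw channel (no normalization)."""
    if config is None:
        config = PreprocessConfig()
    emg = np.asarray(emg, dtype=float)
    if emg.ndim == 1:
        emg = emg[:, None]
    out = np.empty_like(emg)
    upper = config.highpass_upper_hz
    if upper is not None and upper >= rate / 2.0:
        upper = None  # band limit not representable at this rate
    for j in range(emg.shape[1]):
        x = highpass_zero_phase(
            emg[:, j], rate, config.order, config.highpass_cutoff_hz, upper
        )
        x = rectify(x)
        out[:, j] = lowpass_envelope(
            x, rate, config.order, step_period_s, config.envelope_cutoff_scale
        )
    return out


def normalize_and_align(
    envelopes: list[np.ndarray],
    emg_times: list[np.ndarray],
    angle_times: list[np.ndarray],
) -> list[EnvelopeSeries]:
    """Divide each channel by its maximum over ALL trials, then interpolate
    onto each trial's angle time grid.

    The normalization scope is the whole list (one subject's trials); a
    channel that is identically zero across every trial cannot be
    normalized and raises.  Small filtfilt undershoots below zero are
    clipped so the result stays in [0, 1].
    """
    if not envelopes:
        raise InvalidInputError("need at least one trial to normalize")
    n_ch = envelopes[0].shape[1]
    maxima = np.zeros(n_ch)
    for env in envelopes:
        if env.shape[1] != n_ch:
            raise InvalidInputError("all trials must have the same channel count")
        maxima = np.maximum(maxima, env.max(axis=0))
    if np.any(maxima <= 0):
        bad = int(np.argmax(maxima <= 0))
        raise DegenerateDataError(
            f"channel {bad} is identically zero (or negative) across all trials"
        )
    out = []
    for env, t_emg, t_ang in zip(envelopes, emg_times, angle_times):
        normed = np.clip(env / maxima, 0.0, 1.0)
        aligned = np.column_stack(
            [np.interp(t_ang, t_emg, normed[:, j]) for j in range(n_ch)]
        )
        out.append(
            EnvelopeSeries(
                e=aligned, time=np.asarray(t_ang, dtype=float),
                normalization_max=maxima.copy(),
            )
        )
    return out


def extract_envelopes(trials, config: PreprocessConfig | None = None):
    """Full pipeline over a list of GaitTrial: filter/rectify/low-pass each
    trial's raw EMG, normalize across all trials, align to each angle grid.

    The step period of each trial is its mean gait-cycle duration computed
    from ``cycle_bounds``.  Returns a dict trial_id -> EnvelopeSeries.
    """
    raw_envs, emg_times, angle_times = [], [], []
    for trial in trials:
        durations = [
            (end - start) / trial.angle_rate for start, end in trial.cycle_bounds
        ]
        step_period = float(np.mean(durations))
        raw_envs.append(
            envelope_from_raw(trial.emg, trial.emg_rate, step_period, config)
        )
        emg_times.append(trial.emg_time)
        angle_times.append(trial.angle_time)
    series = normalize_and_align(raw_envs, emg_times, angle_times)
    return {trial.trial_id: s for trial, s in zip(trials, series)}
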