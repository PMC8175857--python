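"""Synthetic treadmill-gait generator.

Emulates the structure of public treadmill gait recordings so the whole
pipeline (preprocessing, activation dynamics, GP / GP-NARX prediction,
speed-scenario evaluation) is testable without external downloads:

* periodic knee-flexion trajectories built from a small number of
  harmonics, whose offset, amplitude and timing vary deterministically
  with treadmill speed;
* a reciprocal antagonist pair — the extensor (vastus lateralis) envelope
  is a raised-cosine bump around stance, the flexor (semimembranosus)
  around swing — phase-locked to the gait cycle;
* raw sEMG synthesized as band-limited (20-450 Hz) white Gaussian noise
  amplitude-modulated by the activation envelope, so the standard
  rectify-and-low-pass pipeline approximately recovers the envelope;
* additive Gaussian measurement noise on the angle trace.

This generator is entirely synthetic plumbing: it produces signals with the
statistical structure the prediction method assumes, not a biomechanical
simulation.  Determinism: one master seed; per-trial and per-purpose
sub-seeds are spawned with ``np.random.SeedSequence(master, spawn_key)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activation_dynamics import ActivationParams, activation_from_envelope
from .errors import InvalidConfigError, InvalidInputError

__all__ = ["GaitSimConfig", "GaitTrial", "simulate_cycle_angle", "simulate_emg",
           "generate_dataset"]

# raw-EMG carrier band (Hz); standard surface-EMG signal band
_CARRIER_BAND = (20.0, 450.0)


@dataclass(frozen=True)
class GaitSimConfig:
    """Configuration of the synthetic gait dataset.

    Defaults mirror a running-treadmill protocol: four speeds with five
    gait cycles each, knee angle at 100 Hz, EMG at 1000 Hz.
    """

    speeds: tuple = (2.0, 3.0, 4.0, 5.0)
    cycles_per_speed: int = 5
    angle_rate: int = 100
    emg_rate: int = 1000
    angle_harmonics: int = 3
    emg_noise_floor: float = 0.05
    measurement_noise_deg: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.speeds or any(s <= 0 for s in self.speeds):
            raise InvalidConfigError("speeds must be positive")
        if self.cycles_per_speed < 5:
            raise InvalidConfigError("cycles_per_speed must be at least 5")
        if self.emg_rate % self.angle_rate != 0:
            raise InvalidConfigError(
                "emg_rate must be an integer multiple of angle_rate"
            )
        if self.angle_harmonics < 1:
            raise InvalidConfigError("angle_harmonics must be >= 1")
        if not (0.0 <= self.emg_noise_floor < 1.0):
            raise InvalidConfigError("emg_noise_floor must lie in [0, 1)")
        if self.measurement_noise_deg < 0:
            raise InvalidConfigError("measurement_noise_deg must be non-negative")


@dataclass
class GaitTrial:
    """One gait recording: raw EMG, angle trace, cycle segmentation.

    ``cycle_bounds`` are 0-based half-open ``(start, end)`` index pairs
    into the angle vector, sorted, non-overlapping and contiguous.
    """

    trial_id: str
    speed: float
    emg: np.ndarray          # [n_emg x 2], arbitrary units, zero-mean
    emg_time: np.ndarray
    angle: np.ndarray        # degrees
    angle_time: np.ndarray
    cycle_bounds: list       # [(start, end), ...]
    angle_rate: float
    emg_rate: float
    ground_truth_activation: np.ndarray | None = None  # simulator only

    def validate(self) -> None:
        from .errors import TrialFormatError

        if self.angle.size == 0:
            raise TrialFormatError("angle vector is empty")
        if not np.all(np.isfinite(self.angle)):
            raise TrialFormatError("angle contains non-finite values")
        for name, t, rate in (
            ("emg_time", self.emg_time, self.emg_rate),
            ("angle_time", self.angle_time, self.angle_rate),
        ):
            dt = np.diff(t)
            if t.size > 1 and (np.any(dt <= 0) or not np.allclose(dt, 1.0 / rate, rtol=1e-6)):
                raise TrialFormatError(
                    f"{name} is not strictly increasing with constant step 1/{rate}"
                )
        prev_end = None
        for start, end in self.cycle_bounds:
            if not (0 <= start < end <= self.angle.size):
                raise TrialFormatError("cycle bounds out of range")
            if prev_end is not None:
                if start < prev_end:
                    raise TrialFormatError("cycle bounds overlap")
                if start != prev_end:
                    raise TrialFormatError("cycle bounds are not contiguous")
            prev_end = end
        if self.emg.ndim != 2 or self.emg.shape[1] != 2:
            raise TrialFormatError("emg must be an [n x 2] matrix")
        if self.emg.shape[0] != self.emg_time.size:
            raise TrialFormatError("emg row count does not match emg_time")
        if self.angle.size != self.angle_time.size:
            raise TrialFormatError("angle length does not match angle_time")


def _harmonic_coefficients(speed: float, harmonics: int, seed: int):
    """Deterministic speed-dependent Fourier coefficients for the knee
    trajectory, with a small seed-controlled subject-level jitter shared
    across speeds."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(901,)))
    amp_jitter = rng.uniform(0.9, 1.1, size=harmonics)
    phase_jitter = rng.uniform(-0.25, 0.25, size=harmonics)
    offset = 32.0 + 3.0 * speed
    amps = np.array(
        [(14.0 + 2.2 * speed) * 0.35**h for h in range(harmonics)]
    ) * amp_jitter
    phases = np.array(
        [np.pi * (0.3 + 0.15 * h) + 0.02 * speed for h in range(harmonics)]
    ) + phase_jitter
    return offset, amps, phases


def simulate_cycle_angle(
    speed: float, phase: np.ndarray, harmonics: int, seed: int = 0
) -> np.ndarray:
    """Smooth periodic knee-flexion trajectory over one gait cycle.

    ``phase`` is gait-cycle phase in [0, 1).  The trajectory is a sum of
    ``harmonics`` cosines whose offset, amplitudes and phases vary
    deterministically with speed, kept within the physiological flexion
    range [0, 90] degrees.
    """
    if harmonics < 1:
        raise InvalidConfigError("harmonics must be >= 1")
    phase = np.asarray(phase, dtype=float)
    if phase.size and (np.min(phase) < 0 or np.max(phase) >= 1.0):
        raise InvalidInputError("phase values must lie in [0, 1)")
    if phase.size > 1 and np.any(np.diff(phase) < 0):
        raise InvalidInputError("phase must be sorted")
    offset, amps, phases = _harmonic_coefficients(speed, harmonics, seed)
    angle = np.full(phase.shape, offset)
    for h in range(harmonics):
        angle += amps[h] * np.cos(2.0 * np.pi * (h + 1) * phase + phases[h])
    lo, hi = float(np.min(angle, initial=offset)), float(np.max(angle, initial=offset))
    if lo < 0.0 or hi > 90.0:  # affine rescale into range; keeps smoothness
        angle = 2.0 + (angle - lo) * (86.0 / max(hi - lo, 1e-9))
    return angle


def simulate_emg(
    activation_envelope: np.ndarray,
    emg_rate: float,
    noise_floor: float,
    seed: int,
    envelope_rate: float = 100.0,
) -> np.ndarray:
    """Raw sEMG as amplitude-modulated band-limited Gaussian noise.

    The carrier is white Gaussian noise band-passed to 20-450 Hz (or to
    0.45 x Nyquist when the rate is too low) and normalized to unit sample
    standard deviation; the instantaneous amplitude is
    ``noise_floor + (1 - noise_floor) * envelope`` with the envelope
    linearly upsampled from ``envelope_rate`` to ``emg_rate``.
    """
    from scipy.signal import butter, sosfiltfilt

    env = np.asarray(activation_envelope, dtype=float)
    if env.size and (np.min(env) < 0 or np.max(env) > 1):
        raise InvalidInputError("activation envelope must lie in [0, 1]")
    n_env = env.size
    factor = emg_rate / envelope_rate
    n_out = int(round(n_env * factor))
    t_env = np.arange(n_env) / envelope_rate
    t_out = np.arange(n_out) / emg_rate
    env_up = np.interp(t_out, t_env, env)

    rng = np.random.default_rng(seed)
    carrier = rng.standard_normal(n_out)
    nyq = emg_rate / 2.0
    hi = min(_CARRIER_BAND[1], 0.9 * nyq)
    sos = butter(4, [_CARRIER_BAND[0], hi], btype="bandpass", fs=emg_rate, output="sos")
    carrier = sosfiltfilt(sos, carrier)
    sd = carrier.std()
    if sd > 0:
        carrier = carrier / sd
    return carrier * (noise_floor + (1.0 - noise_floor) * env_up)


def _raised_cosine(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine bump on the circle: 1 at ``center``, 0 outside a
    window of total width ``width`` (in cycle fraction)."""
    d = np.mod(phase - center + 0.5, 1.0) - 0.5
    out = np.zeros_like(phase)
    inside = np.abs(d) < width / 2.0
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * d[inside] / width))
    return out


def _cycle_duration_s(speed: float) -> float:
    # faster running -> shorter stride time; clipped to a plausible range
    return float(np.clip(1.4 - 0.12 * speed, 0.5, 1.5))


def generate_dataset(config: GaitSimConfig) -> list[GaitTrial]:
    """Generate one trial per speed, each with ``cycles_per_speed`` cycles.

    The extensor envelope peaks in stance (phase ~0.15), the flexor in
    swing (phase ~0.65) — a reciprocal antagonist pattern.  The stored
    ``ground_truth_activation`` is the default activation-dynamics chain
    applied to the noiseless envelopes, i.e. the quantity the EMG pipeline
    is supposed to recover.
    """
    trials = []
    act_params = ActivationParams()
    upsample = config.emg_rate // config.angle_rate
    for i, speed in enumerate(config.speeds):
        n_cycle = int(round(_cycle_duration_s(speed) * config.angle_rate))
        phase_cycle = np.arange(n_cycle) / n_cycle
        angle_cycle = simulate_cycle_angle(
            speed, phase_cycle, config.angle_harmonics, config.seed
        )
        n_angle = n_cycle * config.cycles_per_speed
        angle = np.tile(angle_cycle, config.cycles_per_speed)
        phase = np.tile(phase_cycle, config.cycles_per_speed)

        amp = min(1.0, 0.6 + 0.08 * speed)
        env_ext = amp * _raised_cosine(phase, center=0.15, width=0.55)
        env_flex = amp * _raised_cosine(phase, center=0.65, width=0.55)
        # channel order matches the trial bundle: [semimembranosus (flexor),
        # vastus lateralis (extensor)]
        env = np.column_stack([env_flex, env_ext])

        angle_time = np.arange(n_angle) / config.angle_rate
        truth = activation_from_envelope(env, angle_time, act_params).a

        emg_cols = []
        for ch in range(2):
            sub = np.random.SeedSequence(config.seed, spawn_key=(i, ch))
            emg_cols.append(
                simulate_emg(
                    env[:, ch],
                    config.emg_rate,
                    config.emg_noise_floor,
                    sub,
                    envelope_rate=config.angle_rate,
                )
            )
        emg = np.column_stack(emg_cols)
        emg_time = np.arange(n_angle * upsample) / config.emg_rate

        noise_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(i, 99))
        )
        angle_noisy = angle + noise_rng.standard_normal(n_angle) * config.measurement_noise_deg

        trial = GaitTrial(
            trial_id=f"speed_{speed:g}",
            speed=float(speed),
            emg=emg,
            emg_time=emg_time,
            angle=angle_noisy,
            angle_time=angle_time,
            cycle_bounds=[(c * n_cycle, (c + 1) * n_cycle) for c in range(config.cycles_per_speed)],
            angle_rate=float(config.angle_rate),
            emg_rate=float(config.emg_rate),
            ground_truth_activation=truth,
        )
        trial.validate()
        trials.append(trial)
    return trials
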