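"""On-disk trial bundles: one directory per gait trial.

Layout::

    <trial>/
      metadata.json          trial_id, speed, rates, cycle_bounds, channels
      emg.csv                time_s, emg_semimembranosus, emg_vastus_lateralis
      angle.csv              time_s, knee_angle_deg
      activation_truth.csv   optional (simulated trials only)

CSV files carry a header row, comma separators and '.' decimals; floats are
written with 17 significant digits so a write/read round-trip is lossless
at test tolerance.  ``cycle_bounds`` indices are 0-based half-open into the
angle vector.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, TrialFormatError
from .synthetic_gait import GaitTrial

__all__ = ["EMG_CHANNELS", "read_trial", "write_trial"]

EMG_CHANNELS = ("emg_semimembranosus", "emg_vastus_lateralis")
ACT_CHANNELS = ("act_semimembranosus", "act_vastus_lateralis")
ANGLE_CHANNEL = "knee_angle_deg"
_FLOAT_FMT = "%.17g"


def write_trial(trial: GaitTrial, path: str | Path) -> Path:
    """Write a validated GaitTrial as a bundle directory; returns the path."""
    if trial.angle.size == 0:
        raise InvalidInputError("refusing to write a trial with an empty angle vector")
    trial.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "trial_id": trial.trial_id,
        "speed_m_s": trial.speed,
        "angle_rate_hz": trial.angle_rate,
        "emg_rate_hz": trial.emg_rate,
        "cycle_bounds": [[int(s), int(e)] for s, e in trial.cycle_bounds],
        "emg_channels": list(EMG_CHANNELS),
        "angle_channel": ANGLE_CHANNEL,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    emg_df = pd.DataFrame(
        {"time_s": trial.emg_time, EMG_CHANNELS[0]: trial.emg[:, 0],
         EMG_CHANNELS[1]: trial.emg[:, 1]}
    )
    emg_df.to_csv(path / "emg.csv", index=False, float_format=_FLOAT_FMT)
    angle_df = pd.DataFrame({"time_s": trial.angle_time, ANGLE_CHANNEL: trial.angle})
    angle_df.to_csv(path / "angle.csv", index=False, float_format=_FLOAT_FMT)
    if trial.ground_truth_activation is not None:
        act_df = pd.DataFrame(
            {"time_s": trial.angle_time,
             ACT_CHANNELS[0]: trial.ground_truth_activation[:, 0],
             ACT_CHANNELS[1]: trial.ground_truth_activation[:, 1]}
        )
        act_df.to_csv(path / "activation_truth.csv", index=False, float_format=_FLOAT_FMT)
    return path


def _read_numeric_csv(fn: Path, expected_cols: list[str]) -> pd.DataFrame:
    if not fn.exists():
        raise FileNotFoundError(f"missing file: {fn}")
    df = pd.read_csv(fn)
    if list(df.columns) != expected_cols:
        raise TrialFormatError(
            f"{fn.name}: columns {list(df.columns)} do not match metadata "
            f"channel names {expected_cols}"
        )
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialFormatError(
                f"{fn.name}: non-numeric value in column '{col}' at data row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise TrialFormatError(f"{fn.name}: missing value in column '{col}' at data row {row}")
        df[col] = numeric
    return df


def read_trial(path: str | Path) -> GaitTrial:
    """Load and fully validate a trial bundle."""
    path = Path(path)
    meta_fn = path / "metadata.json"
    if not meta_fn.exists():
        raise FileNotFoundError(f"missing file: {meta_fn}")
    meta = json.loads(meta_fn.read_text())
    emg_cols = ["time_s"] + list(meta["emg_channels"])
    emg_df = _read_numeric_csv(path / "emg.csv", emg_cols)
    angle_df = _read_numeric_csv(path / "angle.csv", ["time_s", meta["angle_channel"]])

    truth = None
    act_fn = path / "activation_truth.csv"
    if act_fn.exists():
        act_df = _read_numeric_csv(act_fn, ["time_s"] + list(ACT_CHANNELS))
        truth = act_df[list(ACT_CHANNELS)].to_numpy()

    angle_rate = float(meta["angle_rate_hz"])
    emg_rate = float(meta["emg_rate_hz"])
    n_angle = len(angle_df)
    duration = n_angle / angle_rate
    expected_emg = int(round(duration * emg_rate))
    if len(emg_df) != expected_emg:
        raise TrialFormatError(
            f"emg.csv row count {len(emg_df)} inconsistent with declared rates "
            f"(expected {expected_emg} for {duration:g} s at {emg_rate:g} Hz)"
        )

    bounds = [(int(s), int(e)) for s, e in meta["cycle_bounds"]]
    for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
        if s2 < e1:
            raise TrialFormatError("cycle bounds overlap")

    trial = GaitTrial(
        trial_id=str(meta["trial_id"]),
        speed=float(meta["speed_m_s"]),
        emg=emg_df[list(meta["emg_channels"])].to_numpy(),
        emg_time=emg_df["time_s"].to_numpy(),
        angle=angle_df[meta["angle_channel"]].to_numpy(),
        angle_time=angle_df["time_s"].to_numpy(),
        cycle_bounds=bounds,
        angle_rate=angle_rate,
        emg_rate=emg_rate,
        ground_truth_activation=truth,
    )
    trial.validate()
    return trial
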