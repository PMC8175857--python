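"""Evaluation protocol: NRMSE / CC metrics, the three speed-scenario
data-allocation strategies, one-way ANOVA model comparison, and the
end-to-end experiment runner.

Metrics (computed on de-normalized, degree-scale predictions):

    NRMSE = sqrt(mean((y_est - y_real)^2)) / max|y_real|
    CC    = cov(y_est, y_real) / (sd(y_est) sd(y_real))

Allocation scenarios for a dataset with one trial per treadmill speed:

* ``speed_dependent`` — per speed: first 3 cycles train, last 2 test;
* ``multi_speed`` — first 3 cycles of every speed pooled as training,
  the last 2 cycles of each speed as per-speed test sets;
* ``speed_independent`` — leave-one-speed-out: the last 2 cycles of one
  speed in turn as test, the first 3 cycles of every other speed as
  training.

A ``dataset2`` style with 10-cycle blocks (train cycles 0-9, test 10-19
per speed, and the corresponding pooled / leave-one-out variants) is
provided for long recordings.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .activation_dynamics import ActivationParams, activation_from_envelope
from .errors import DegenerateDataError, InvalidInputError
from .narx_gp import (
    GPTrainConfig,
    LagSpec,
    predict_osa,
    predict_static,
    train_narx_from_segments,
    train_static_from_segments,
)
from .preprocess import PreprocessConfig, extract_envelopes

__all__ = [
    "SCENARIOS",
    "AllocationPlan",
    "Split",
    "EvaluationReport",
    "ExperimentConfig",
    "nrmse",
    "cc",
    "allocate",
    "one_way_anova",
    "run_experiment",
]

SCENARIOS = ("speed_dependent", "multi_speed", "speed_independent")


def nrmse(y_est: np.ndarray, y_real: np.ndarray) -> float:
    """Root-mean-square error divided by the maximum magnitude of the
    actual values."""
    y_est = np.asarray(y_est, dtype=float).ravel()
    y_real = np.asarray(y_real, dtype=float).ravel()
    if y_est.shape != y_real.shape or y_est.size < 1:
        raise InvalidInputError("series must be non-empty and of equal length")
    y_max = float(np.max(np.abs(y_real)))
    if y_max == 0.0:
        raise DegenerateDataError("all-zero reference series: NRMSE normalizer undefined")
    return float(np.sqrt(np.mean((y_est - y_real) ** 2)) / y_max)


def cc(y_est: np.ndarray, y_real: np.ndarray) -> float:
    """Pearson correlation coefficient between predicted and actual series."""
    y_est = np.asarray(y_est, dtype=float).ravel()
    y_real = np.asarray(y_real, dtype=float).ravel()
    if y_est.shape != y_real.shape or y_est.size < 2:
        raise InvalidInputError("series must be of equal length >= 2")
    if np.std(y_est) == 0.0 or np.std(y_real) == 0.0:
        raise DegenerateDataError("correlation undefined for a constant series")
    return float(np.corrcoef(y_est, y_real)[0, 1])


@dataclass
class Split:
    """One train/test split: (trial_id, cycle indices) lists plus a label."""

    train: list  # [(trial_id, [cycle_idx, ...]), ...]
    test: list
    label: str


@dataclass
class AllocationPlan:
    scenario: str
    splits: list  # list[Split]


def _check_cycles(trials, minimum: int) -> None:
    for t in trials:
        if len(t.cycle_bounds) < minimum:
            raise InvalidInputError(
                f"trial {t.trial_id} (speed {t.speed:g}) has "
                f"{len(t.cycle_bounds)} cycles; allocation needs >= {minimum}"
            )


def allocate(trials, scenario: str, style: str = "dataset1") -> AllocationPlan:
    """Build the train/test plan for one scenario.

    ``dataset1`` style uses 3-train/2-test cycles per speed (needs >= 5
    cycles per speed); ``dataset2`` style uses 10-cycle blocks (needs >=
    20)."""
    if scenario not in SCENARIOS:
        raise InvalidInputError(f"unknown scenario '{scenario}'")
    if style == "dataset1":
        n_train, test_slice = 3, "last2"
        _check_cycles(trials, 5)
        train_of = lambda t: (t.trial_id, list(range(3)))
        test_of = lambda t: (t.trial_id, [len(t.cycle_bounds) - 2, len(t.cycle_bounds) - 1])
    elif style == "dataset2":
        _check_cycles(trials, 20)
        train_of = lambda t: (t.trial_id, list(range(10)))
        test_of = lambda t: (t.trial_id, list(range(10, 20)))
    else:
        raise InvalidInputError(f"unknown allocation style '{style}'")

    splits = []
    if scenario == "speed_dependent":
        for t in trials:
            splits.append(Split(train=[train_of(t)], test=[test_of(t)],
                                label=f"speed={t.speed:g}"))
    elif scenario == "multi_speed":
        pooled = [train_of(t) for t in trials]
        for t in trials:
            splits.append(Split(train=list(pooled), test=[test_of(t)],
                                label=f"speed={t.speed:g}"))
    else:  # speed_independent
        for t in trials:
            others = [train_of(o) for o in trials if o.trial_id != t.trial_id]
            if not others:
                raise InvalidInputError("speed_independent needs >= 2 speeds")
            splits.append(Split(train=others, test=[test_of(t)],
                                label=f"heldout_speed={t.speed:g}"))
    for s in splits:
        train_set = {(tid, c) for tid, cs in s.train for c in cs}
        test_set = {(tid, c) for tid, cs in s.test for c in cs}
        assert not (train_set & test_set), "train/test cycle sets overlap"
        assert test_set, "empty test set"
    return AllocationPlan(scenario=scenario, splits=splits)


def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value."""
    if len(groups) < 2:
        raise InvalidInputError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    for g in arrays:
        if g.size < 2:
            raise InvalidInputError("each ANOVA group needs at least 2 values")
        if not np.all(np.isfinite(g)):
            raise InvalidInputError("ANOVA groups must be finite")
    if np.ptp(np.concatenate(arrays)) == 0:
        # all values identical in every group: no variance at all
        return 0.0, 1.0
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):
        return 0.0, 1.0
    return float(f), float(p)


@dataclass(frozen=True)
class ExperimentConfig:
    """All tunables of the end-to-end evaluation protocol."""

    preprocess: PreprocessConfig = PreprocessConfig()
    activation: ActivationParams = ActivationParams()
    lags: LagSpec = LagSpec(2, 2)
    gp_train: GPTrainConfig = GPTrainConfig(n_restarts=1, maxiter=100)
    style: str = "dataset1"
    scenarios: tuple = SCENARIOS
    seed: int = 0


@dataclass
class SplitResult:
    scenario: str
    label: str
    model: str  # "GP" or "NARX-GP"
    nrmse: float
    cc: float
    n_test: int


@dataclass
class EvaluationReport:
    """Per-split metrics, per-scenario aggregates and ANOVA comparisons."""

    per_split: list  # list[SplitResult]
    scenario_summary: dict  # scenario -> model -> {mean_nrmse, std_nrmse, ...}
    anova: dict  # scenario -> {"F": f, "p": p}; plus "overall"
    config: dict
    seed: int
    timings_s: dict = field(default_factory=dict)

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame([asdict(r) for r in self.per_split])

    def to_dict(self) -> dict:
        return {
            "per_split": [asdict(r) for r in self.per_split],
            "scenario_summary": self.scenario_summary,
            "anova": self.anova,
            "config": self.config,
            "seed": self.seed,
            "timings_s": self.timings_s,
        }


def _segments_for(plan_entries, trials_by_id, activations):
    """Turn (trial_id, cycle list) selections into contiguous
    (activation, angle_deg) segments; consecutive cycle indices in the
    same trial are merged so lag windows can span them, but windows never
    straddle a selection boundary."""
    segments = []
    for trial_id, cycles in plan_entries:
        trial = trials_by_id[trial_id]
        act = activations[trial_id]
        cycles = sorted(cycles)
        run_start = 0
        for i in range(1, len(cycles) + 1):
            if i == len(cycles) or cycles[i] != cycles[i - 1] + 1:
                first, last = cycles[run_start], cycles[i - 1]
                lo = trial.cycle_bounds[first][0]
                hi = trial.cycle_bounds[last][1]
                segments.append((act.a[lo:hi], trial.angle[lo:hi]))
                run_start = i
    return segments


def run_experiment(trials, config: ExperimentConfig | None = None) -> EvaluationReport:
    """Run the full protocol: preprocess -> activation dynamics -> train
    GP and NARX-GP per split -> predict on test cycles -> metrics,
    per-scenario aggregation and ANOVA between the two models' NRMSE."""
    if config is None:
        config = ExperimentConfig()
    t0 = _time.perf_counter()
    timings: dict = {}

    trials_by_id = {t.trial_id: t for t in trials}
    envelopes = extract_envelopes(trials, config.preprocess)
    activations = {
        tid: activation_from_envelope(env.e, env.time, config.activation)
        for tid, env in envelopes.items()
    }
    timings["preprocess"] = _time.perf_counter() - t0

    per_split: list[SplitResult] = []
    anova: dict = {}
    scenario_summary: dict = {}
    split_counter = 0
    for scenario in config.scenarios:
        t_sc = _time.perf_counter()
        plan = allocate(trials, scenario, config.style)
        nrmse_gp, nrmse_narx = [], []
        for split in plan.splits:
            train_segs = _segments_for(split.train, trials_by_id, activations)
            test_segs = _segments_for(split.test, trials_by_id, activations)
            seed_gp = config.seed * 10000 + split_counter * 2
            seed_narx = seed_gp + 1
            split_counter += 1
            try:
                static = train_static_from_segments(
                    train_segs, config=config.gp_train, seed=seed_gp
                )
                narx = train_narx_from_segments(
                    train_segs, config.lags, config=config.gp_train, seed=seed_narx
                )
                est_s, real_s, est_n, real_n = [], [], [], []
                for a_seg, y_seg in test_segs:
                    res_s = predict_static(static, a_seg)
                    est_s.append(res_s.y_hat)
                    real_s.append(y_seg)
                    res_n = predict_osa(narx, a_seg, y_seg)
                    est_n.append(res_n.y_hat)
                    real_n.append(np.asarray(y_seg)[res_n.k_index])
                est_s, real_s = np.concatenate(est_s), np.concatenate(real_s)
                est_n, real_n = np.concatenate(est_n), np.concatenate(real_n)
            except Exception as exc:
                raise type(exc)(
                    f"[scenario={scenario}, split={split.label}] {exc}"
                ) from exc
            r_gp = SplitResult(scenario, split.label, "GP",
                               nrmse(est_s, real_s), cc(est_s, real_s), est_s.size)
            r_nx = SplitResult(scenario, split.label, "NARX-GP",
                               nrmse(est_n, real_n), cc(est_n, real_n), est_n.size)
            per_split += [r_gp, r_nx]
            nrmse_gp.append(r_gp.nrmse)
            nrmse_narx.append(r_nx.nrmse)
        f, p = one_way_anova([nrmse_gp, nrmse_narx])
        anova[scenario] = {"F": f, "p": p}
        scenario_summary[scenario] = {}
        for model in ("GP", "NARX-GP"):
            vals_nrmse = [r.nrmse for r in per_split
                          if r.scenario == scenario and r.model == model]
            vals_cc = [r.cc for r in per_split
                       if r.scenario == scenario and r.model == model]
            scenario_summary[scenario][model] = {
                "mean_nrmse": float(np.mean(vals_nrmse)),
                "std_nrmse": float(np.std(vals_nrmse, ddof=1)) if len(vals_nrmse) > 1 else 0.0,
                "mean_cc": float(np.mean(vals_cc)),
                "std_cc": float(np.std(vals_cc, ddof=1)) if len(vals_cc) > 1 else 0.0,
            }
        timings[scenario] = _time.perf_counter() - t_sc
    all_gp = [r.nrmse for r in per_split if r.model == "GP"]
    all_nx = [r.nrmse for r in per_split if r.model == "NARX-GP"]
    f, p = one_way_anova([all_gp, all_nx])
    anova["overall"] = {"F": f, "p": p}
    timings["total"] = _time.perf_counter() - t0
    return EvaluationReport(
        per_split=per_split,
        scenario_summary=scenario_summary,
        anova=anova,
        config={
            "preprocess": asdict(config.preprocess),
            "activation": asdict(config.activation),
            "lags": asdict(config.lags),
            "gp_train": {
                "init": asdict(config.gp_train.init),
                "n_restarts": config.gp_train.n_restarts,
                "maxiter": config.gp_train.maxiter,
                "optimize": config.gp_train.optimize,
            },
            "style": config.style,
            "scenarios": list(config.scenarios),
        },
        seed=config.seed,
        timings_s=timings,
    )
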