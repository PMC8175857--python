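# Methods

This note documents the models, the numerical choices, and what the
synthetic data does and does not establish.

## Muscle activation dynamics

Processed sEMG `e(t) ∈ [0, 1]` is converted to neural activation with a
delayed second-order recursion

    q_k = α e_{k−d} − β₁ q_{k−1} − β₂ q_{k−2},

parameterized by its roots γ₁, γ₂ (β₁ = γ₁ + γ₂, β₂ = γ₁γ₂). Stability
requires |γᵢ| < 1; the gain is tied to the recursion coefficients as
α = 1 + β₁ + β₂ so that a constant envelope `c` drives `q → c` (unit
steady-state gain). Muscle activation is the exponential shaping

    a(q) = (e^{Aq} − 1) / (e^{A} − 1),   A ∈ [−3, 0),

monotone with a(0) = 0, a(1) = 1; A → 0⁻ approaches linearity and A = 0 is
rejected as singular. The published literature on this model family does
not pin down one coefficient set for the knee; the defaults here are
γ₁ = γ₂ = −0.5 (critically damped-ish second-order response), zero
electromechanical delay at the 100 Hz angle rate, and A = −1. All are
exposed in `ActivationParams`. Transients of the recursion can overshoot
[0, 1] slightly; `q` is clipped by default (`clip=False` disables this).

## EMG preprocessing

Per channel: 4th-order zero-phase Butterworth high-pass at 40 Hz (the
stated purpose is removing low-frequency motion artifact; an optional
upper corner turns it into a band-pass and is off by default), full-wave
rectification, 4th-order zero-phase Butterworth low-pass with cutoff
`3.5 / step period` where the step period is the trial's mean gait-cycle
duration from `cycle_bounds`, then division by the per-channel maximum
over **all** trials of the subject (one dataset directory = one subject).
Zero-phase filtering is forward–backward (`sosfiltfilt`); the quoted order
is the design order per pass, so effective attenuation is doubled — the
standard convention in gait work. The envelope is finally interpolated
linearly onto the angle time grid (it is band-limited far below the angle
Nyquist, so this is effectively decimation). Filtfilt undershoot below
zero is clipped so e(t) stays in [0, 1].

## Gaussian-process core

Isotropic squared-exponential kernel (single length scale; no ARD), and a
constant prior mean equal to the training-target mean — the minimal choice
consistent with the generic-mean posterior formulas. `K_Y = K + σ_n²I` is
factorized by Cholesky; posterior mean/variance, the log marginal
likelihood and its analytic gradient all reuse the triangular factor, and
the matrix is never inverted explicitly (the gradient does form `K_Y⁻¹`
once via triangular solves for the trace term; the exact-GP cost is
O(N³) per evaluation).

Numerical policy: hyperparameters live in log space with bounds
[1e−6, 1e6]; σ_n has a floor of 1e−6 during optimization. A jitter ladder
1e−10 → 1e−6 is tried when the factorization of `K_Y` fails — but only
when σ_n > 0. With σ_n exactly 0, a singular kernel matrix (e.g.
duplicated inputs) is an error, not something to paper over: jitter exists
to absorb roundoff, not rank deficiency.

Optimization is L-BFGS-B on the negative log marginal likelihood with the
analytic gradient (the standard quasi-Newton realization of
gradient-ascent maximum-likelihood estimation), default 3 restarts from
±1-nat log-uniform perturbations of the initial point; the returned θ is
never worse than the initial one because the initial point is kept as a
candidate. Full-Bayesian inference over hyperparameters is deliberately
not implemented — point estimation is the intended regime.

## Static GP and NARX-GP predictors

Targets are min–max normalized to [0, 1] with training-set extrema, stored
for exact inversion back to degrees. The NARX regressor at time k is
`[u_k, u_{k−1}, …, u_{k−n_u}, y_{k−1}, …, y_{k−n_y}]` — the *current*
input is included, output lags start at 1 — with default n_u = n_y = 2,
matching the second-order character of the activation dynamics; with two
muscles that is 8 columns. One-step-ahead prediction always uses measured
output lags (never fed-back predictions), so prediction at time k depends
only on inputs up to k and outputs up to k−1; the first
`max(n_u, n_y)` samples of each contiguous segment are warm-up and are not
predicted. Design rows from multiple cycles or trials are concatenated,
and lag windows never straddle a segment boundary.

The reported standard deviation adds the observation-noise variance σ_n²
to the latent posterior variance, so `μ ± 2σ` is a predictive interval for
a new *measurement* (nominal 95.45 % coverage); this is the band the
calibration check targets. Free-run multi-step simulation with uncertainty
propagation is out of scope.

## Evaluation protocol

NRMSE divides the RMS error by `max |y_real|` of the evaluated test
segment (per split, not global); CC is the Pearson correlation. Both are
computed on de-normalized, degree-scale predictions over the concatenated
test cycles of a split, then averaged across splits for scenario means.
Allocation (dataset-1 style, one trial per speed with ≥ 5 cycles):
speed-dependent = first 3 cycles train / last 2 test per speed;
multi-speed = pooled first-3 of every speed train, per-speed last-2 test;
speed-independent = last 2 cycles of the held-out speed test, first 3 of
every other speed train. A dataset-2 style with 10-cycle blocks is
available for long recordings (≥ 20 cycles per speed). Model comparison is
a classical one-way ANOVA (no Welch correction) on the per-split NRMSE of
the two models, significance at p < 0.05.

Inside `run_experiment` the per-split hyperparameter optimization uses 1
restart and at most 100 L-BFGS iterations — pilot runs showed additional
restarts change the metrics only in the fourth decimal on this problem
while tripling the cost; the library-level default for
`optimize_hyperparameters` remains 3 restarts.

## Synthetic gait generator

The generator emulates the structure of treadmill running data: per speed,
a periodic knee-flexion trajectory summing ≤ 4 harmonics whose offset,
amplitude and timing vary deterministically with speed (kept inside
[0°, 90°]; cycle duration shrinks with speed, 1.16 s at 2 m/s to 0.8 s at
5 m/s at the default 100 Hz angle rate); reciprocal raised-cosine
activation envelopes (extensor centred at stance phase 0.15, flexor at
swing phase 0.65, width 0.55 cycles, amplitude growing with speed); raw
EMG as white Gaussian noise band-passed to 20–450 Hz, normalized to unit
std, and amplitude-modulated by
`noise_floor + (1 − noise_floor)·envelope` at 1000 Hz; and additive
Gaussian angle noise (default std 0.5°, a typical marker-derived joint
angle accuracy). Defaults are four speeds (2–5 m/s) × five cycles.
Determinism: one master seed; sub-streams are spawned as
`SeedSequence(master, spawn_key=(trial_index, channel))` (99 for angle
noise, 901 for trajectory-shape jitter).

The stored `ground_truth_activation` is the activation-dynamics chain
applied to the noiseless envelopes — exactly the quantity the EMG pipeline
should recover; on the default configuration the recovered activation
correlates > 0.98 with it, which is what makes the end-to-end comparison
meaningful.

What the generator does **not** model: biomechanics (no joint moments or
ground-reaction forces), inter-cycle kinematic variability, EMG crosstalk,
electrode artifacts, or pathology beyond what a per-leg amplitude scaling
could express. Consequently, passing end-to-end tests demonstrates that
the pipeline's stages compose correctly and that the NARX-GP's advantage
over the static GP holds under the assumed signal structure — it does not
certify error magnitudes on real recordings.

## Problem sizes and known limitations

The default evaluation trains GPs on ~250–1200 points per split (three
scenarios, 4 splits each, two models), chosen so the full protocol runs in
about two minutes on one CPU. Exact GPs scale as O(N³); applying the
package to long recordings (dataset-2 style, tens of cycles per speed)
will want subsampling or a sparse approximation, which is not provided.
The static GP's error on synthetic data is dominated by the
non-injectivity of the activation→angle map over the cycle, so its NRMSE
here (~0.18) should not be read as an estimate for any particular real
dataset. Model serialization to disk is limited to the evaluation report
(JSON); trained predictors are retrained from data rather than persisted.
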