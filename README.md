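# kneegp

sEMG-driven knee-joint-angle prediction with Gaussian-process (GP) and
GP-NARX models.

Surface electromyography (sEMG) leads joint motion, which makes it a
natural control signal for rehabilitation robotics and exoskeletons — but
the neuromusculoskeletal system is noisy and uncertain, so a point
prediction of the joint angle is not enough. `kneegp` implements a
non-parametric, probabilistic predictor of knee flexion angle from the sEMG
of one antagonist muscle pair (semimembranosus = flexor, vastus lateralis =
extensor). It is aimed at researchers in EMG-driven motion modelling who
want a compact, fully inspectable reference implementation with calibrated
uncertainty bands.

## Method

1. **Feature extraction.** Raw sEMG is band-limited with a 4th-order
   zero-phase Butterworth high-pass at 40 Hz, full-wave rectified,
   low-pass filtered (4th order, cutoff `3.5 / step period`), and
   max-normalized over all trials, giving the processed signal *e(t)*.
   Muscle activation dynamics then map *e(t)* through a stable
   second-order recursion to neural activation *q(t)* and through the
   exponential shaping nonlinearity
   `a(q) = (e^{Aq} − 1)/(e^{A} − 1)` to muscle activation *a(t) ∈ [0, 1]*.

2. **GP regression.** With the squared-exponential kernel
   `k(x, x′) = σ_f² exp(−‖x − x′‖² / 2σ_l²)` and observation noise σ_n,
   the posterior at test inputs X\* is

       μ* = K(X*, X) [K(X, X) + σ_n²I]⁻¹ (y − μ) + μ
       Σ* = K(X*, X*) − K(X*, X) [K(X, X) + σ_n²I]⁻¹ K(X, X*)

   Hyperparameters θ = (σ_f, σ_l, σ_n) are point-estimated by maximizing
   the log marginal likelihood with its analytic gradient (L-BFGS in log
   space, Cholesky-based linear algebra throughout).

3. **Predictors.** The *static GP* maps the instantaneous activation pair
   `u_k = [a_{1,k}, a_{2,k}]ᵀ` to the angle `y_k`. The *NARX-GP* performs
   one-step-ahead (OSA) prediction from lagged inputs and lagged
   **measured** outputs,

       y*_k = f(u_k, …, u_{k−n_u}, y_{k−1}, …, y_{k−n_y}),   n_u = n_y = 2,

   and reports a `μ ± 2σ` predictive band.

4. **Evaluation.** NRMSE (`RMS error / max |y_real|`) and Pearson CC over
   three gait-cycle allocation scenarios — speed-dependent, multi-speed,
   and speed-independent (leave-one-speed-out) — with a one-way ANOVA
   comparing the two models' NRMSE.

Because the treadmill datasets this kind of method is usually evaluated on
are external downloads, the package ships a synthetic gait generator
(`kneegp.synthetic_gait`) producing speed-dependent periodic knee
trajectories, reciprocal antagonist activation envelopes, and raw EMG as
amplitude-modulated band-limited noise — enough statistical structure to
exercise every stage of the pipeline end to end.

## Worked example

```bash
kneegp simulate --out data/ --speeds 2.0,4.0 --seed 2
kneegp evaluate --data data/ --out report.json --scenario speed_dependent
```

prints (per-split NRMSE and CC, then the model comparison):

```
speed_dependent speed=2      GP 0.185184 0.526773     232
speed_dependent speed=2 NARX-GP 0.009481 0.999057     230
speed_dependent speed=4      GP 0.187130 0.575535     184
speed_dependent speed=4 NARX-GP 0.007967 0.999398     182
ANOVA [speed_dependent]: F = 20724.630, p = 4.82e-05
```

Read: the static GP leaves ~18–19 % normalized error because the mapping
from instantaneous activation to angle is not one-to-one over the gait
cycle, while the NARX-GP's one-step-ahead predictions track the measured
angle to within ~1 % NRMSE with correlation > 0.999; the difference is
statistically significant at p < 0.05. Add `--plot fig.png` to draw the
measured angle against both predictions with the NARX-GP `μ ± 2σ` band.

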