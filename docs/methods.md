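# Methods

## Estimand and observed data

The estimand is the risk function `F(t) = P(T ≤ t)` over a follow-up window
`[0, τ]`, with survival `S(t) = 1 − F(t)`; competing events are assumed
absent. The main study observes the error-prone, right-censored pair
`(W* = min(W, C), η = 1{W ≤ C})` for each subject, where `W` is the
error-prone event time and `C` the censoring time. A validation sample
additionally carries the gold pair `(T* = min(T, C), δ = 1{T ≤ C})` with
the *same* censoring time per subject (enforced as an invariant for doubly
censored records).

## The corrected estimator

With `a(t) = P(W ≤ t | T ≤ t)` and `b(t) = P(W ≤ t | T > t)`, the naive
Kaplan-Meier curve estimates the mixture
`F_W(t) ≈ a(t)F(t) + b(t)(1 − F(t))`, so inverting pointwise and taking a
running supremum gives

    F̂(t) = sup over v ≤ t of (F̂_W(v) − b(v)) / (a(v) − b(v)).

Implementation details, all of which matter in finite samples:

* The supremum is evaluated over the naive curve's jump grid plus a `t = 0`
  anchor of 0. All functions involved are step-constant between jumps, so
  this enumeration is exact, not an approximation.
* Where `a(v) − b(v) ≤ 0` the pointwise value falls back to `F̂_W(v)`
  (per time point, not globally); the count of such points is reported in
  the curve's metadata.
* The anchor floors the output at 0; after the supremum the values are
  clamped to at most 1. The raw ratio can leave `[0, 1]` in finite samples
  and clamping keeps the estimand interpretable; the metadata flags when
  clamping was active.
* With `a ≡ 1, b ≡ 0` the estimator reproduces the naive curve bit-for-bit.

## Estimating a(t) and b(t) from validation data

**Nonparametric.** At each ranked observed event time `R_k` of the *main*
study,

    â(R_k) = Σ 1{W*_i ≤ R_k, T*_i ≤ R_k} δ_i η_i / Σ 1{T*_i ≤ R_k} δ_i
    b̂(R_k) = Σ 1{W*_i ≤ R_k, T*_i > R_k} η_i / Σ 1{T*_i > R_k},

with the empty-denominator conventions `â = 1`, `b̂ = 0` (adopted globally,
including left of the first grid point). Both are computed with sorted-key
counting, O((m + K) log m).

**Parametric.** Three constants are estimated from the validation sample by
classifying each record against a time-equality tolerance `tol`
(default 0 — exact equality, which is what the synthetic generator and
date-matched registry data produce):

* *on time*: `η = 1, δ = 1, |W* − T*| ≤ tol`;
* *false positive / early*: `η = 1, W* < T* − tol` (and false positives
  registered at the censoring time of a nonevent);
* *late*: `η = 1, δ = 1, W* > T* + tol`;
* *missed*: `δ = 1, η = 0`.

Then `θ̂` = on-time count / gold events **not preceded by a false positive**
(the conditioning matters: dropping it biases the corrected estimator
upward by ~2 pp when false positives and missed events coexist);
`λ̂_fp` = false positives / person-time from 0 to min(false-positive time,
T*, C) — exposure to a false positive ends at the true event;
`λ̂_D` = late detections / person-time from the true event to
min(detection, C), accumulated over late *and* missed (never-detected)
events, making it a censored-exponential rate estimator. A rate with zero
event count is 0; a positive count with zero person-time is an error. When
no gold events exist, `θ̂ = 1` by analogy with the `â = 1` convention.

The parametric forms are `b̂(t) = 1 − exp(−λ̂_fp t)` and
`â(t) = x̂ + ŷ + ẑ` with

    ŷ(t) = 1 − exp(−λ̂_fp t/2)            (false positive before T)
    x̂(t) = θ̂ (1 − ŷ(t))                  (on-time detection)
    ẑ(t) = (1 − exp(−λ̂_D t/2))(1 − x̂ − ŷ)  (late detection),

where the unknown true event time is set midway through `[0, t]`. This
midpoint device makes `â` an approximation under any real event-time
distribution; the scenario study below quantifies the residual bias
(well under half a percentage point at the end of follow-up).

## Uncertainty

**Validation bootstrap.** Each of `B` replicates resamples `n` main-study
records and `m` validation records with replacement, refits `a`/`b` in the
resampled validation data, and recomputes the corrected curve on the
replicate's own grid, evaluated on the point estimate's grid. The replicate
SD is the pointwise SE; 95% limits are Wald on the risk scale, truncated to
`[0, 1]`. With *internal* validation data the main-study resampling is
stratified by membership and the resampled members are reused as the
replicate's validation records (the literal reading of stratified
resampling); this requires the validation rows to be aligned, in order,
with the flagged main-study records. Defaults: `B = 1000` for analysis;
the scaled-down test harness uses `B = 200`. Replicates where the
denominator fallback fires are retained, matching the estimator's own
conventions.

**Expert mode.** Beta priors are placed on `θ`, `G(τ)` and `Q(s)`; each
replicate resamples the main study, draws the three probabilities,
back-calculates `λ_fp = −log(1 − G)/τ` and `λ_D = −log(1 − Q)/s` under
constant hazards, and recomputes the parametric correction. Draws of
exactly 1 (infinite rate) are rejected and redrawn, with a log record. The
95% limits are the 2.5th/97.5th replicate percentiles; the point curve uses
the prior means. Binomial inflation of the priors is left to the analyst.

## Synthetic-data generator

True times follow `F(t) = 1 − exp(−(λt)^α)` with shape `α = 2` (increasing
hazard). Rates are calibrated by `λ = (−log(1 − p))^{1/α} / t`: 20%
two-year risk for the main cohort (`λ = 0.236`) and 35% for the validation
cohort (`λ = 0.328`), reflecting validation sampling enriched for high-risk
subjects. Censoring: with probability 0.5 a subject draws
`C ~ Uniform(0, τ)`, otherwise `C = τ = 2` years. Cohort sizes default to
`n = 5000`, `m = 2500`.

Measurement error is induced per subject from `(θ, λ_fp, λ_D)` in six
scenarios (A: 1/0/0, B: 0.7/0/0, C: 0.7/0/0.3, D: 1/0.1/0, E: 0.7/0.1/0,
F: 0.7/0.1/0.3). Two mechanisms are provided:

* **registry** (default) — mimics record-linkage error: a subject receives
  a false registry match with probability `λ_fp·τ/2` at a
  `Uniform(0, τ)` time, effective only if it precedes the true event; a
  true event is detected at its true time with probability `θ` if no false
  positive struck first; a single registry sweep at an
  `Exponential(λ_D)` time from the origin catches a missed event only if
  the sweep falls after it. Missed events are never rescued by a later
  false positive. Under this mechanism the person-time estimators recover
  *effective* rates (e.g. `λ̂_fp ≈ 0.052` when the nominal parameter is
  0.1) — which is precisely why the parametric correction stays unbiased:
  the fitted forms match the data-generating `a`/`b`, not the nominal
  labels. Implied naive-estimator biases at `τ` are −6.0 (B), −5.2 (C),
  +8.0 (D), +2.4 (E) and +3.1 (F) percentage points.
* **exponential** — competing constant-hazard clocks (false-positive time
  `~ Exp(λ_fp)` from the origin, late-detection delay `~ Exp(λ_D)` after a
  missed event). Under this mechanism the parametric estimators are
  exactly correctly specified and `estimate_params` recovers the
  generating triple; it backs the parameter-recovery and consistency
  tests.

What the generator does **not** emulate: covariate-dependent measurement
error, time-varying `θ`, dependent censoring, competing risks, and
event-time rounding/heaping as seen in real registries. Passing tests
therefore demonstrate correctness of the estimators under the stated error
models, not robustness to arbitrary real-world linkage behaviour.

## Scenario harness and metrics

Each replicate generates a main and a validation cohort, induces error in
both, and applies four estimators: naive KM on `(W*, η)`; KM on the
validation gold data alone; and the nonparametric and parametric corrected
estimators. Risk is evaluated on an evenly spaced grid of 8 time points
(`τ/8` to `τ`) plus the `τ`-restricted mean survival time (exact step
integral of `S`). Reported per estimator and time point: bias
(100 × mean(estimate − truth); negative = underestimation), relative bias,
empirical SE (SD of estimates ×100), average estimated SE,
`RMSE = sqrt(bias² + ESE²)` (an identity by construction), `SER = ASE/ESE`,
and 95% CI coverage — Greenwood Wald for the uncorrected estimators (the
standard default; the naive coverage check passes under it), bootstrap Wald
for the corrected ones when a bootstrap size is requested.

Default replicate counts are scaled to a single CPU: 500 in the test suite
(tolerances are the stated bound plus 3× the Monte-Carlo SE of the
replicated mean), 1,000 in `scripts/acceptance.py`, 200 × `B = 200` for the
corrected-estimator coverage check. Robustness options implemented as
generator switches: validation hazard shape `α = 0.5` (decreasing) and a
mismeasured-gold mode that applies an error triple to the validation gold
measurements.

## Known limitations

* The nonparametric estimator inherits validation-sample noise at every
  grid point; with small `m` and multiple error types its finite-sample
  bias and variance exceed the naive estimator's (use the parametric form).
* Wald intervals on the risk scale can behave poorly near 0 and 1; no
  transformation is applied.
* The time-equality tolerance for "on-time" classification defaults to
  exact equality; data with rounded dates need a positive `tol`.
* `θ`, `λ_fp`, `λ_D` are treated as time-constant; piecewise re-estimation
  within user-supplied bins is a natural extension and is not implemented.
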