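# rgsurv

Risk and survival functions corrected for **outcome measurement error** in
right-censored time-to-event data.

Epidemiological cohorts often ascertain outcomes through imperfect channels —
linkage to a death registry, self-report, diagnoses scraped from electronic
records. The recorded event time `W` can then disagree with the true time
`T`: events are missed entirely, registered at the wrong (usually later)
time, or invented outright by a false match. A Kaplan-Meier curve computed
from such error-prone times is biased, and the bias grows over follow-up.

`rgsurv` implements a longitudinal extension of the Rogan-Gladen estimator
that corrects the whole risk function. It is aimed at epidemiologists and
biostatisticians who have (i) a main study with error-prone event times and
(ii) either a validation sample carrying both gold-standard and error-prone
measurements, or elicitable expert knowledge about the measurement process.

## The estimator

Let `F(t) = P(T ≤ t)` be the target risk function and `F̂_W(t)` the naive
Kaplan-Meier estimate computed from the error-prone times. Define the
longitudinal sensitivity/false-positive analogues

    a(t) = P(W ≤ t | T ≤ t)        b(t) = P(W ≤ t | T > t).

The corrected estimator is

    F̂(t) = sup { (F̂_W(v) − b(v)) / (a(v) − b(v)) : 0 ≤ v ≤ t },

with the running supremum enforcing monotonicity; wherever the denominator
is nonpositive the pointwise value falls back to `F̂_W(v)`. At a single time
point with perfect time measurement this is exactly the classical
Rogan-Gladen correction of a misclassified proportion.

`a(t)` and `b(t)` can be supplied three ways:

* **nonparametric** — step estimators computed from validation data at each
  observed event time of the main study;
* **parametric** — three interpretable constants estimated from validation
  data by person-time arithmetic: `θ` (probability an event is detected at
  its true time, given no earlier false positive), `λ_fp` (false-positive
  rate among the event-free) and `λ_D` (late-detection rate after a missed
  event), combined as `b(t) = 1 − exp(−λ_fp t)` and
  `a(t) = x(t) + y(t) + z(t)` with the unknown true event time set midway
  through `[0, t]`;
* **expert knowledge** — Beta priors on `θ`, on the cumulative
  false-positive probability `G(τ)` and on the detection probability
  `Q(s)`, with rates back-calculated as `λ = −log(1 − p)/horizon` and
  propagated by Monte Carlo (quantitative bias analysis).

Uncertainty comes from a bootstrap that resamples the main study and the
validation data together (stratified by membership when the validation
sample is internal).

## Worked example

Simulated registry-linkage cohort: 5,000 subjects, true two-year mortality
risk 20% (Weibull, increasing hazard), 50% early censoring; only 70% of
deaths are caught at their true date and false registry matches accrue at
rate 0.1/year. A validation sample of 2,500 higher-risk subjects (35%
two-year risk) carries both measurements.

```python
import numpy as np
from rgsurv import (ScenarioConfig, bootstrap_corrected_risk, estimate_params,
                    km_risk, generate_cohort, induce_error)
from rgsurv.simulation import validation_from

cfg = ScenarioConfig.scenario("E")          # theta=0.7, lambda_fp=0.1
rng = np.random.default_rng(42)
main_cohort = generate_cohort(cfg.n, cfg.alpha, cfg.rate_main, cfg.tau, cfg.censor_prob, rng)
main_obs = induce_error(main_cohort, cfg.theta, cfg.lambda_fp, cfg.lambda_d, rng, cfg.tau)
val_cohort = generate_cohort(cfg.m, cfg.alpha, cfg.rate_val, cfg.tau, cfg.censor_prob, rng)
val_obs = induce_error(val_cohort, cfg.theta, cfg.lambda_fp, cfg.lambda_d, rng, cfg.tau)
val = validation_from(val_cohort, val_obs)

naive = km_risk(main_obs, horizon=cfg.tau)
params = estimate_params(val)
res = bootstrap_corrected_risk(main_obs, val, mode="parametric", B=500, seed=7)
```

prints (via the obvious formatting):

```
naive KM risk at 2 y:     0.228
theta_hat = 0.680, lambda_fp_hat = 0.0574, lambda_d_hat = 0.0000
corrected risk at 2 y:    0.203 (SE 0.018, 95% CI 0.168-0.238)
true Weibull risk at 2 y: 0.200
```

The naive curve overshoots the truth by ~3 percentage points (false
positives outweigh missed deaths here); the corrected estimate lands on the
true 20% at the cost of a wider interval. Note `λ̂_fp ≈ 0.057` is the
*effective* constant false-positive hazard recovered from this registry-like
error process, not the scenario's nominal 0.1 — the correction only needs
the fitted `a`/`b` to match the data, which they do.

The same analysis runs from the shell on CSV files:

```
rgsurv estimate --main main.csv --validation val.csv \
       --mode parametric --bootstrap 1000 --seed 1 --out corrected.csv
rgsurv params val.csv
rgsurv simulate --scenario E --reps 500 --seed 1 --out metrics.csv
rgsurv sensitivity --main main.csv --config priors.yaml --out qba.csv
```

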