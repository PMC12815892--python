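"""Synthetic-cohort generator and scenario harness.

The generator emulates a registry-linkage mortality study: true event times
are Weibull with increasing hazard (shape alpha = 2), follow-up ends at an
administrative horizon tau = 2 years, and half the cohort is censored early
at a Uniform(0, tau) time.  The main cohort is calibrated to 20% risk at
2 years and the (higher-risk) validation cohort to 35%.

Measurement error is induced per subject from three parameters: theta
(on-time detection probability), lambda_fp (false-positive rate) and
lambda_d (late-detection rate), in six standard scenarios:

====  =====  =========  ========
name  theta  lambda_fp  lambda_d
====  =====  =========  ========
A     1.0    0.0        0.0
B     0.7    0.0        0.0
C     0.7    0.0        0.3
D     1.0    0.1        0.0
E     0.7    0.1        0.0
F     0.7    0.1        0.3
====  =====  =========  ========

Two error mechanisms are available (see ``induce_error``): the default
"registry" mechanism mimics record-linkage error (a false registry match
occurring with probability lambda_fp*tau/2 at a Uniform(0, tau) time, and a
single registry sweep at an Exponential(lambda_d) time that catches missed
events occurring before it); the "exponential" mechanism uses competing
constant-hazard clocks (false-positive time ~ Exp(lambda_fp), late-detection
delay ~ Exp(lambda_d) after a missed event), under which the constant-rate
parametric estimators are exactly correctly specified and the generating
(theta, lambda_fp, lambda_d) are recovered by ``estimate_params``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .correction import corrected_risk
from .misclassification import (MisclassModel, ValidationSample, estimate_params)
from .risk import RiskCurve, SurvivalSample, km_risk, rmst
from .uncertainty import bootstrap_corrected_risk

__all__ = [
    "SCENARIOS", "ScenarioConfig", "Cohort", "MetricsTable",
    "weibull_rate_for_target", "true_risk", "true_rmst",
    "generate_cohort", "induce_error", "validation_from",
    "run_scenario", "pseudo_rmse",
]

#: (theta, lambda_fp, lambda_d) for the six standard error scenarios.
SCENARIOS: dict[str, tuple[float, float, float]] = {
    "A": (1.0, 0.0, 0.0),
    "B": (0.7, 0.0, 0.0),
    "C": (0.7, 0.0, 0.3),
    "D": (1.0, 0.1, 0.0),
    "E": (0.7, 0.1, 0.0),
    "F": (0.7, 0.1, 0.3),
}

ESTIMATORS = ("naive", "validation_only", "nonparametric", "parametric")

Mechanism = Literal["registry", "exponential"]


def weibull_rate_for_target(alpha: float, t: float, risk: float) -> float:
    """Rate lambda solving 1 - exp(-(lambda t)^alpha) = risk.

    Calibrates the Weibull CDF F(t) = 1 - exp(-(lambda t)^alpha) to a target
    cumulative risk at time t; e.g. alpha=2, 20% at 2 years gives 0.236.
    """
    if alpha <= 0 or t <= 0:
        raise ValueError("alpha and t must be positive")
    if not 0.0 < risk < 1.0:
        raise ValueError("target risk must lie strictly between 0 and 1")
    return (-np.log1p(-risk)) ** (1.0 / alpha) / t


def true_risk(t, alpha: float, rate: float):
    """Weibull cumulative risk F(t) = 1 - exp(-(rate t)^alpha)."""
    return -np.expm1(-(rate * np.asarray(t, dtype=float)) ** alpha)


def true_rmst(horizon: float, alpha: float, rate: float, n_grid: int = 20001) -> float:
    """Restricted mean survival time of the Weibull truth (Simpson quadrature)."""
    t = np.linspace(0.0, horizon, n_grid)
    s = np.exp(-(rate * t) ** alpha)
    h = t[1] - t[0]
    return float(h / 3.0 * (s[0] + s[-1] + 4 * s[1:-1:2].sum() + 2 * s[2:-1:2].sum()))


@dataclass(frozen=True)
class ScenarioConfig:
    """Inputs for one simulation scenario.

    Defaults reproduce the standard study conditions: main cohort of 5,000 at
    20% two-year risk, validation cohort of 2,500 at 35%, Weibull shape 2,
    50% early uniform censoring, horizon 2 years.
    """

    n: int = 5000
    m: int = 2500
    alpha: float = 2.0
    alpha_val: float | None = None        # validation shape; None -> same as main
    risk_main: float = 0.20
    risk_val: float = 0.35
    tau: float = 2.0
    censor_prob: float = 0.5
    theta: float = 1.0
    lambda_fp: float = 0.0
    lambda_d: float = 0.0
    mechanism: Mechanism = "registry"
    #: optional (theta, lambda_fp, lambda_d) error applied to the validation
    #: *gold* measurements (the "mismeasured gold standard" robustness check)
    gold_error: tuple[float, float, float] | None = None
    reps: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n, self.m, self.reps) < 1:
            raise ValueError("n, m and reps must be at least 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.censor_prob <= 1.0:
            raise ValueError("censor_prob must lie in [0, 1]")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.lambda_fp < 0 or self.lambda_d < 0:
            raise ValueError("rates must be nonnegative")

    @property
    def rate_main(self) -> float:
        return weibull_rate_for_target(self.alpha, self.tau, self.risk_main)

    @property
    def rate_val(self) -> float:
        alpha = self.alpha if self.alpha_val is None else self.alpha_val
        return weibull_rate_for_target(alpha, self.tau, self.risk_val)

    @classmethod
    def scenario(cls, name: str, **overrides) -> "ScenarioConfig":
        theta, lfp, ld = SCENARIOS[name.upper()]
        return cls(theta=theta, lambda_fp=lfp, lambda_d=ld, **overrides)


@dataclass(frozen=True)
class Cohort:
    """Latent truth for a simulated cohort: true event times (possibly beyond
    the censoring time) and censoring times, plus the gold observed sample."""

    true_time: np.ndarray
    censor_time: np.ndarray

    @property
    def gold(self) -> SurvivalSample:
        t_star = np.minimum(self.true_time, self.censor_time)
        delta = (self.true_time <= self.censor_time).astype(np.int8)
        return SurvivalSample(time=t_star, event=delta)


def generate_cohort(n: int, alpha: float, rate: float, tau: float,
                    censor_prob: float, rng: np.random.Generator) -> Cohort:
    """Draw a cohort: Weibull true times and uniform/administrative censoring."""
    u = rng.random(n)
    true_time = (-np.log(u)) ** (1.0 / alpha) / rate
    censor = np.full(n, tau)
    early = rng.random(n) < censor_prob
    censor[early] = rng.uniform(0.0, tau, int(early.sum()))
    return Cohort(true_time=true_time, censor_time=censor)


def induce_error(cohort: Cohort, theta: float, lambda_fp: float, lambda_d: float,
                 rng: np.random.Generator, tau: float,
                 mechanism: Mechanism = "registry") -> SurvivalSample:
    """Apply outcome measurement error, returning the error-prone (W*, eta).

    Common to both mechanisms: a true event is detected at its true time with
    probability theta, provided no false positive struck first; false
    positives only strike subjects still event-free (they occur strictly
    before T); a missed event is never rescued by a later false positive.

    * ``registry``: each subject receives a false registry match with
      probability lambda_fp*tau/2 at a time Uniform(0, tau); a single registry
      sweep at time ~ Exponential(lambda_d) from the origin detects a missed
      event only if the sweep falls after the true event time.
    * ``exponential``: false-positive time ~ Exponential(lambda_fp) from the
      origin; a missed event is detected after a delay ~ Exponential(lambda_d)
      from the true event time.
    """
    n = cohort.true_time.size
    t, c = cohort.true_time, cohort.censor_time

    if mechanism == "registry":
        p_fp = min(lambda_fp * tau / 2.0, 1.0)
        has_fp = rng.random(n) < p_fp if p_fp > 0 else np.zeros(n, dtype=bool)
        fp_time = np.where(has_fp, rng.uniform(0.0, tau, n), np.inf)
        if lambda_d > 0:
            sweep = rng.exponential(1.0 / lambda_d, n)
            late_time = np.where(sweep > t, sweep, np.inf)
        else:
            late_time = np.full(n, np.inf)
    elif mechanism == "exponential":
        if lambda_fp > 0:
            fp_time = rng.exponential(1.0 / lambda_fp, n)
        else:
            fp_time = np.full(n, np.inf)
        if lambda_d > 0:
            late_time = t + rng.exponential(1.0 / lambda_d, n)
        else:
            late_time = np.full(n, np.inf)
    else:
        raise ValueError(f"unknown mechanism: {mechanism!r}")

    on_time = rng.random(n) < theta
    detect = np.where(on_time, t, late_time)
    fp_strikes = fp_time < t
    w = np.where(fp_strikes, fp_time, detect)
    w_star = np.minimum(w, c)
    eta = (w <= c).astype(np.int8)
    return SurvivalSample(time=w_star, event=eta)


def validation_from(cohort: Cohort, obs: SurvivalSample) -> ValidationSample:
    """Pair a cohort's gold sample with its error-prone sample."""
    gold = cohort.gold
    return ValidationSample(gold_time=gold.time, gold_event=gold.event,
                            obs_time=obs.time, obs_event=obs.event)


def _gold_with_error(cohort: Cohort, error: tuple[float, float, float],
                     rng: np.random.Generator, tau: float,
                     mechanism: Mechanism) -> SurvivalSample:
    """Mismeasured 'gold standard' for the robustness check."""
    th, lfp, ld = error
    return induce_error(cohort, th, lfp, ld, rng, tau, mechanism)


@dataclass
class MetricsTable:
    """Simulation performance metrics.

    ``risk``: per estimator x time point — truth, bias (x100), relative bias,
    ESE, ASE, RMSE = sqrt(bias^2 + ESE^2), SER = ASE/ESE, coverage.
    ``rmst``: per estimator — truth and bias of the tau-restricted mean
    survival time, in years and days.
    """

    risk: pd.DataFrame
    rmst: pd.DataFrame
    config: ScenarioConfig | None = None

    def at(self, estimator: str, time: float) -> pd.Series:
        df = self.risk
        row = df[(df["estimator"] == estimator) & (np.isclose(df["time"], time))]
        return row.iloc[0]


def pseudo_rmse(estimate: float, gold_estimate: float, se: float) -> float:
    """sqrt((estimate - gold)^2 + se^2): benchmarking error against a
    gold-standard analysis whose truth is itself an estimate."""
    if se < 0:
        raise ValueError("se must be nonnegative")
    return float(np.sqrt((estimate - gold_estimate) ** 2 + se ** 2))


def _greenwood_ci_covers(curve: RiskCurve, t: float, truth: float) -> tuple[float, bool]:
    """(SE, covered) for a KM curve's Greenwood Wald 95% CI at time t."""
    if curve.grid.size == 0 or t < curve.grid[0]:
        se = 0.0
        est = 0.0
    else:
        idx = int(np.searchsorted(curve.grid, t, side="right")) - 1
        se = float(curve.se[idx]) if curve.se is not None else 0.0
        est = float(curve.values[idx])
    lo, hi = max(est - 1.96 * se, 0.0), min(est + 1.96 * se, 1.0)
    return se, (lo <= truth <= hi)


def run_scenario(config: ScenarioConfig,
                 estimators: Sequence[str] = ESTIMATORS,
                 eval_times: Iterable[float] | None = None,
                 coverage_B: int = 0,
                 seed: int | np.random.Generator | None = None) -> MetricsTable:
    """Monte-Carlo comparison of the four risk estimators under one scenario.

    Per replicate: generate a main and a validation cohort, induce measurement
    error in both, and apply the requested estimators at ``eval_times``
    (default: an evenly spaced grid of 8 points, tau/8 to tau) plus the
    tau-restricted mean survival time.  Coverage uses Greenwood Wald 95%
    intervals for the naive and validation-only estimators and — when
    ``coverage_B`` > 0 — bootstrap Wald intervals with ``coverage_B``
    replicates for the corrected estimators.
    """
    unknown = set(estimators) - set(ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimator(s): {sorted(unknown)}")
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tau = config.tau
    if eval_times is None:
        eval_times = np.linspace(tau / 8.0, tau, 8)
    eval_times = np.asarray(list(eval_times), dtype=float)

    truth_risk = true_risk(eval_times, config.alpha, config.rate_main)
    truth_rmst = true_rmst(tau, config.alpha, config.rate_main)
    alpha_val = config.alpha if config.alpha_val is None else config.alpha_val

    est_list = list(estimators)
    R, K = config.reps, eval_times.size
    estimates = {e: np.empty((R, K)) for e in est_list}
    rmsts = {e: np.empty(R) for e in est_list}
    ses = {e: np.full((R, K), np.nan) for e in est_list}
    covered = {e: np.full((R, K), np.nan) for e in est_list}

    for r in range(R):
        main_cohort = generate_cohort(config.n, config.alpha, config.rate_main,
                                      tau, config.censor_prob, rng)
        main_obs = induce_error(main_cohort, config.theta, config.lambda_fp,
                                config.lambda_d, rng, tau, config.mechanism)
        val_cohort = generate_cohort(config.m, alpha_val, config.rate_val,
                                     tau, config.censor_prob, rng)
        val_obs = induce_error(val_cohort, config.theta, config.lambda_fp,
                               config.lambda_d, rng, tau, config.mechanism)
        if config.gold_error is not None:
            val_gold = _gold_with_error(val_cohort, config.gold_error, rng,
                                        tau, config.mechanism)
            val = ValidationSample(gold_time=val_gold.time, gold_event=val_gold.event,
                                   obs_time=val_obs.time, obs_event=val_obs.event)
        else:
            val = validation_from(val_cohort, val_obs)

        naive_curve = km_risk(main_obs, horizon=tau)
        curves: dict[str, RiskCurve] = {}
        if "naive" in est_list:
            curves["naive"] = naive_curve
        if "validation_only" in est_list:
            gold_sample = val_cohort.gold if config.gold_error is None else val_gold
            curves["validation_only"] = km_risk(gold_sample, horizon=tau)
        if "nonparametric" in est_list:
            model_np = MisclassModel.nonparametric(val, naive_curve.grid)
            curves["nonparametric"] = corrected_risk(naive_curve, model_np)
        if "parametric" in est_list:
            model_p = MisclassModel.from_params(estimate_params(val))
            curves["parametric"] = corrected_risk(naive_curve, model_p)

        for e in est_list:
            curve = curves[e]
            estimates[e][r] = curve(eval_times)
            rmsts[e][r] = rmst(curve, tau)
            if e in ("naive", "validation_only"):
                for j, t in enumerate(eval_times):
                    tr = truth_risk[j]
                    se_j, cov_j = _greenwood_ci_covers(curve, t, tr)
                    ses[e][r, j] = se_j
                    covered[e][r, j] = cov_j
            elif coverage_B > 0:
                boot = bootstrap_corrected_risk(
                    main_obs, val, mode=e, design="external",
                    B=coverage_B, seed=rng)
                boot_vals = boot.point(eval_times)
                idx = np.searchsorted(boot.point.grid, eval_times, side="right") - 1
                se_eval = np.where(idx >= 0, boot.se[np.clip(idx, 0, None)], 0.0)
                lo = np.clip(boot_vals - 1.96 * se_eval, 0.0, 1.0)
                hi = np.clip(boot_vals + 1.96 * se_eval, 0.0, 1.0)
                ses[e][r] = se_eval
                covered[e][r] = (lo <= truth_risk) & (truth_risk <= hi)

    risk_rows = []
    rmst_rows = []
    for e in est_list:
        est = estimates[e]
        bias = 100.0 * (est.mean(axis=0) - truth_risk)
        ese = 100.0 * est.std(axis=0, ddof=1)
        ase = 100.0 * np.nanmean(ses[e], axis=0) if np.any(~np.isnan(ses[e])) else np.full(K, np.nan)
        rmse = np.sqrt(bias ** 2 + ese ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            ser = ase / ese
        cov = (np.nanmean(covered[e], axis=0)
               if np.any(~np.isnan(covered[e])) else np.full(K, np.nan))
        for j, t in enumerate(eval_times):
            risk_rows.append({
                "estimator": e, "time": t, "truth": truth_risk[j],
                "bias": bias[j],
                "relative_bias": bias[j] / (100.0 * truth_risk[j]) if truth_risk[j] > 0 else np.nan,
                "ese": ese[j], "ase": ase[j], "rmse": rmse[j], "ser": ser[j],
                "coverage": cov[j],
                "mc_se": ese[j] / np.sqrt(R),
            })
        rmst_bias = rmsts[e].mean() - truth_rmst
        rmst_rows.append({
            "estimator": e, "truth_years": truth_rmst,
            "bias_years": rmst_bias, "bias_days": rmst_bias * 365.25,
            "mc_se_days": rmsts[e].std(ddof=1) / np.sqrt(R) * 365.25,
        })
    return MetricsTable(risk=pd.DataFrame(risk_rows),
                        rmst=pd.DataFrame(rmst_rows), config=config)
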