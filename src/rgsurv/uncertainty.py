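"""Uncertainty for the corrected risk estimator.

Two Monte-Carlo schemes:

* :func:`bootstrap_corrected_risk` — nonparametric bootstrap resampling both
  the main study and the validation data; the replicate standard deviation is
  the standard error and Wald 95% intervals are formed on the risk scale.
  With internal validation data the main-study resampling is stratified by
  validation membership, and the resampled members are reused as the
  replicate's validation records.
* :func:`expert_corrected_risk` — prior-predictive propagation of elicited
  Beta distributions for theta, G(tau) (cumulative false-positive probability
  by end of study) and Q(s) (probability a missed event is detected within s
  time units); rates are back-calculated under constant hazards via
  lambda = -log(1 - p) / horizon.  Percentile 95% intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .correction import corrected_risk, corrected_values
from .misclassification import (MisclassModel, MisclassParams, ValidationSample,
                                a_nonparametric, b_nonparametric, estimate_params)
from .risk import RiskCurve, SurvivalSample, _km_arrays, km_risk

__all__ = ["ExpertPriors", "UncertaintyResult",
           "bootstrap_corrected_risk", "expert_corrected_risk"]

logger = logging.getLogger("rgsurv")

Mode = Literal["parametric", "nonparametric"]
Design = Literal["internal", "external"]


@dataclass(frozen=True)
class ExpertPriors:
    """Beta priors encoding expert knowledge about the measurement process.

    ``theta``: Beta(alpha, beta) for the on-time detection probability.
    ``g``: Beta prior for G(tau), the cumulative false-positive probability by
    the end of study ``tau``.  ``q``: Beta prior for Q(s), the probability a
    missed event is detected within ``s`` time units of the true event.
    """

    theta: tuple[float, float]
    g: tuple[float, float]
    q: tuple[float, float]
    tau: float
    s: float

    def __post_init__(self) -> None:
        for name in ("theta", "g", "q"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} Beta parameters must be positive")
        if self.tau <= 0 or self.s <= 0:
            raise ValueError("tau and s must be positive")


@dataclass
class UncertaintyResult:
    """Corrected curve with pointwise standard errors and 95% bounds."""

    point: RiskCurve
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    method: str
    replicates: int


def rate_from_probability(p: float | np.ndarray, horizon: float) -> float | np.ndarray:
    """Back-calculate a constant hazard from a cumulative probability:
    lambda = -log(1 - p) / horizon."""
    return -np.log1p(-np.asarray(p, dtype=float)) / horizon


def _replicate_curve_values(times: np.ndarray, events: np.ndarray,
                            model: MisclassModel, eval_grid: np.ndarray) -> np.ndarray:
    """Corrected risk of one replicate, evaluated on ``eval_grid``."""
    grid, risk, *_ = _km_arrays(times, events)
    if grid.size == 0:
        return np.zeros_like(eval_grid)
    a = np.asarray(model.a(grid), dtype=float)
    b = np.asarray(model.b(grid), dtype=float)
    values, _ = corrected_values(risk, a, b)
    idx = np.searchsorted(grid, eval_grid, side="right") - 1
    return np.where(idx >= 0, values[np.clip(idx, 0, None)], 0.0)


def _fit_model(val: ValidationSample, mode: Mode, grid: np.ndarray,
               tol: float) -> MisclassModel:
    if mode == "parametric":
        return MisclassModel.from_params(estimate_params(val, tol=tol))
    return MisclassModel.nonparametric(val, grid)


def _resample_validation(val: ValidationSample, idx: np.ndarray) -> ValidationSample:
    return ValidationSample(gold_time=val.gold_time[idx], gold_event=val.gold_event[idx],
                            obs_time=val.obs_time[idx], obs_event=val.obs_event[idx])


def bootstrap_corrected_risk(main: SurvivalSample, val: ValidationSample,
                             mode: Mode = "parametric",
                             design: Design = "external",
                             B: int = 1000,
                             seed: int | np.random.Generator | None = None,
                             val_mask: np.ndarray | None = None,
                             tol: float = 0.0) -> UncertaintyResult:
    """Bootstrap variance for the validation-calibrated corrected estimator.

    Each replicate resamples n main-study records and m validation records
    with replacement, refits a(t)/b(t) in the resampled validation data, and
    recomputes the corrected curve.  ``design="internal"`` requires
    ``val_mask``, a boolean array flagging which main-study records are
    validation members (val rows aligned, in order, with the flagged records);
    members and non-members are then resampled within strata and the sampled
    members are reused as the replicate's validation data.

    The replicate SD is the pointwise standard error; Wald 95% limits
    (point +/- 1.96 SE) are truncated to [0, 1].
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    naive = km_risk(main)
    if naive.grid.size == 0:
        raise ValueError("main sample has no observed events")
    point = corrected_risk(naive, _fit_model(val, mode, naive.grid, tol))
    eval_grid = point.grid

    if design == "internal":
        if val_mask is None:
            raise ValueError("internal design requires val_mask")
        val_mask = np.asarray(val_mask, dtype=bool)
        if val_mask.size != main.n or int(val_mask.sum()) != val.m:
            raise ValueError("val_mask must flag exactly the validation members")
        member_idx = np.flatnonzero(val_mask)
        other_idx = np.flatnonzero(~val_mask)

    reps = np.empty((B, eval_grid.size))
    for k in range(B):
        if design == "external":
            mi = rng.integers(0, main.n, main.n)
            vi = rng.integers(0, val.m, val.m)
            times, events = main.time[mi], main.event[mi]
            val_k = _resample_validation(val, vi)
        else:
            pick_members = member_idx[rng.integers(0, member_idx.size, member_idx.size)]
            pick_others = other_idx[rng.integers(0, other_idx.size, other_idx.size)]
            mi = np.concatenate([pick_members, pick_others])
            times, events = main.time[mi], main.event[mi]
            # reuse the sampled members as the replicate's validation records
            val_positions = np.searchsorted(member_idx, pick_members)
            val_k = _resample_validation(val, val_positions)
        grid_k, risk_k, *_ = _km_arrays(times, events)
        if grid_k.size == 0:
            reps[k] = 0.0
            continue
        model_k = _fit_model(val_k, mode, grid_k, tol)
        a_k = np.asarray(model_k.a(grid_k), dtype=float)
        b_k = np.asarray(model_k.b(grid_k), dtype=float)
        values_k, _ = corrected_values(risk_k, a_k, b_k)
        idx = np.searchsorted(grid_k, eval_grid, side="right") - 1
        reps[k] = np.where(idx >= 0, values_k[np.clip(idx, 0, None)], 0.0)

    se = reps.std(axis=0, ddof=1)
    lo = np.clip(point.values - 1.96 * se, 0.0, 1.0)
    hi = np.clip(point.values + 1.96 * se, 0.0, 1.0)
    logger.info("bootstrap: mode=%s design=%s B=%d fallback_points=%s",
                mode, design, B, point.meta.get("fallback_points"))
    return UncertaintyResult(point=point, se=se, ci_lower=lo, ci_upper=hi,
                             method="wald_bootstrap", replicates=B)


def expert_corrected_risk(main: SurvivalSample, priors: ExpertPriors,
                          B: int = 1000,
                          seed: int | np.random.Generator | None = None) -> UncertaintyResult:
    """Expert-knowledge sensitivity analysis with Monte-Carlo uncertainty.

    Each replicate resamples the main study with replacement, draws
    (theta, G(tau), Q(s)) from their Beta priors, back-calculates lambda_fp
    and lambda_d, and recomputes the corrected curve with the parametric
    a(t)/b(t).  Draws of exactly 1 for G or Q (infinite back-calculated rate)
    are rejected and redrawn.  95% limits are the 2.5th/97.5th replicate
    percentiles; the point curve uses the prior means.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    naive = km_risk(main)
    if naive.grid.size == 0:
        raise ValueError("main sample has no observed events")

    def mean(ab: tuple[float, float]) -> float:
        return ab[0] / (ab[0] + ab[1])

    point_params = MisclassParams(
        theta=mean(priors.theta),
        lambda_fp=float(rate_from_probability(mean(priors.g), priors.tau)),
        lambda_d=float(rate_from_probability(mean(priors.q), priors.s)))
    point = corrected_risk(naive, MisclassModel.from_params(point_params, kind="expert"))
    eval_grid = point.grid

    reps = np.empty((B, eval_grid.size))
    rejected = 0
    for k in range(B):
        mi = rng.integers(0, main.n, main.n)
        while True:
            th = rng.beta(*priors.theta)
            g = rng.beta(*priors.g)
            q = rng.beta(*priors.q)
            if g < 1.0 and q < 1.0:
                break
            rejected += 1
        params_k = MisclassParams(
            theta=min(th, 1.0),
            lambda_fp=float(rate_from_probability(g, priors.tau)),
            lambda_d=float(rate_from_probability(q, priors.s)))
        model_k = MisclassModel.from_params(params_k, kind="expert")
        reps[k] = _replicate_curve_values(main.time[mi], main.event[mi],
                                          model_k, eval_grid)
    if rejected:
        logger.info("expert mode: %d degenerate prior draws rejected and redrawn", rejected)
    se = reps.std(axis=0, ddof=1)
    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    logger.info("expert mode: B=%d fallback_points=%s", B,
                point.meta.get("fallback_points"))
    return UncertaintyResult(point=point, se=se,
                             ci_lower=np.clip(lo, 0.0, 1.0),
                             ci_upper=np.clip(hi, 0.0, 1.0),
                             method="percentile_expert", replicates=B)
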