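"""Nonparametric estimation of risk (cumulative incidence) from right-censored data.

The central object is the risk function F(t) = P(T <= t), the complement of
survival S(t) = 1 - F(t) when competing events are absent.  With right
censoring we observe T* = min(T, C) and the event indicator delta = 1{T <= C};
F is estimated by the Kaplan-Meier product-limit estimator, represented here
as a right-continuous step function (:class:`RiskCurve`) that jumps only at
observed event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "SurvivalSample",
    "RiskCurve",
    "km_risk",
    "eval_risk",
    "rmst",
]


def _as_float_array(x: Any, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored observations: one (time, event) pair per subject.

    ``time`` is the observed follow-up time (event or censoring, same unit
    throughout); ``event`` is 1 if the event was observed at ``time`` and 0 if
    the subject was right-censored there.  The pair may carry either
    gold-standard measurements (T*, delta) or error-prone ones (W*, eta); the
    container does not distinguish.
    """

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = _as_float_array(self.time, "time")
        event = np.atleast_1d(np.asarray(self.event))
        if time.size == 0:
            raise ValueError("no records")
        if time.size != event.size:
            raise ValueError("time and event must have equal length")
        if not np.all(np.isfinite(time)) or np.any(time < 0):
            raise ValueError("times must be finite and nonnegative")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int8))

    @property
    def n(self) -> int:
        return int(self.time.size)


@dataclass
class RiskCurve:
    """Right-continuous, nondecreasing step function F(t) on [0, horizon].

    ``grid`` holds the (strictly increasing) jump times and ``values`` the risk
    at each jump; the value before the first jump is 0 and the last value is
    carried forward beyond the grid.  ``se`` optionally holds a pointwise
    standard error on the same grid.
    """

    grid: np.ndarray
    values: np.ndarray
    horizon: float | None = None
    se: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.grid.size != self.values.size:
            raise ValueError("grid and values must have equal length")
        if self.grid.size and np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.grid.size and (np.any(self.grid < 0) or not np.all(np.isfinite(self.grid))):
            raise ValueError("grid times must be finite and nonnegative")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("risk values must lie in [0, 1]")
        if self.values.size and np.any(np.diff(self.values) < -1e-12):
            raise ValueError("risk values must be nondecreasing")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float).ravel()
            if self.se.size != self.grid.size:
                raise ValueError("se must match grid length")

    def __call__(self, t: Any) -> Any:
        """Evaluate F(t) with right-continuous step semantics."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("evaluation times must be nonnegative")
        if self.grid.size == 0:
            out = np.zeros_like(t_arr, dtype=float)
            return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
        idx = np.searchsorted(self.grid, t_arr, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def step_survival(self) -> np.ndarray:
        """Survival S = 1 - F at each grid point."""
        return 1.0 - self.values


def _km_arrays(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, ...]:
    """Product-limit computation on raw arrays.

    Returns (grid, risk, d, n_at_risk, greenwood_se).  Ties between events and
    censorings at the same time are handled by the standard risk-set
    convention: both remain in the risk set at that time, i.e. events are
    processed before censorings.
    """
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    event_times = t_sorted[e_sorted == 1]
    if event_times.size == 0:
        empty = np.empty(0)
        return empty, empty, empty, empty, empty
    grid, d = np.unique(event_times, return_counts=True)
    n_at_risk = t_sorted.size - np.searchsorted(t_sorted, grid, side="left")
    surv = np.cumprod(1.0 - d / n_at_risk)
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d))); S = 0 => SE 0.
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), 0.0)
    se = surv * np.sqrt(np.cumsum(terms))
    return grid, 1.0 - surv, d.astype(float), n_at_risk.astype(float), se


def km_risk(sample: SurvivalSample, horizon: float | None = None) -> RiskCurve:
    """Kaplan-Meier estimate of the risk function F(t) = 1 - S(t).

    The returned curve jumps at each distinct observed event time t_j with
    product-limit survival prod_{t_j <= t} (1 - d_j / n_j); censoring times
    shape the risk sets n_j but add no jumps.  A sample with no events yields
    a flat zero curve.  Greenwood standard errors for F (= those for S) are
    attached as ``se``.
    """
    grid, risk, d, n_at_risk, se = _km_arrays(sample.time, sample.event)
    if horizon is None:
        horizon = float(sample.time.max())
    return RiskCurve(grid=grid, values=risk, horizon=horizon, se=se,
                     meta={"estimator": "kaplan-meier", "n": sample.n})


def eval_risk(curve: RiskCurve, t: Any) -> Any:
    """Evaluate a risk curve at time(s) ``t`` (right-continuous steps)."""
    return curve(t)


def rmst(curve: RiskCurve, horizon: float) -> float:
    """Restricted mean survival time: the exact step integral of S over [0, horizon]."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if curve.horizon is not None and horizon > curve.horizon + 1e-12:
        raise ValueError("horizon exceeds the curve's follow-up horizon")
    jumps = curve.grid[curve.grid < horizon]
    edges = np.concatenate(([0.0], jumps, [horizon]))
    surv = np.concatenate(([1.0], 1.0 - curve.values[: jumps.size]))
    return float(np.sum(np.diff(edges) * surv))
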