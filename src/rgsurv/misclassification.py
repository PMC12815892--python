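"""Longitudinal sensitivity/specificity analogues a(t) and b(t).

For an error-prone event time W measured in place of the true time T,

* ``a(t) = P(W <= t | T <= t)`` — the probability that a true event occurring
  by t has registered by t (a longitudinal sensitivity), and
* ``b(t) = P(W <= t | T > t)`` — the probability that a subject still
  event-free at t has registered a false-positive event by t (the complement
  analogue of specificity).

Both can be estimated from validation data carrying the gold pair (T*, delta)
and the error-prone pair (W*, eta) per subject, either nonparametrically at
each observed event time, or parametrically through three interpretable
parameters:

* ``theta`` — probability a true event is detected at its true time, given no
  earlier false positive;
* ``lambda_fp`` — constant hazard of a false-positive registration among the
  truly event-free (per time unit);
* ``lambda_d`` — constant hazard of late detection after a missed event.

The parametric a(t) decomposes as x(t) + y(t) + z(t): detection on time,
false positive before the true event, and late detection.  The unknown true
event time inside y and z is approximated by the midpoint t/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .risk import _as_float_array

__all__ = [
    "ValidationSample",
    "MisclassParams",
    "MisclassModel",
    "a_nonparametric",
    "b_nonparametric",
    "estimate_params",
    "classify_records",
    "b_parametric",
    "y_component",
    "x_component",
    "z_component",
    "a_parametric",
]


@dataclass(frozen=True)
class ValidationSample:
    """Paired gold-standard and error-prone measurements per subject.

    ``gold_time``/``gold_event`` hold (T*, delta) and ``obs_time``/``obs_event``
    hold (W*, eta).  Censoring is shared: a subject censored in both versions
    must carry the same censoring time.
    """

    gold_time: np.ndarray
    gold_event: np.ndarray
    obs_time: np.ndarray
    obs_event: np.ndarray

    def __post_init__(self) -> None:
        gt = _as_float_array(self.gold_time, "gold_time")
        ot = _as_float_array(self.obs_time, "obs_time")
        ge = np.atleast_1d(np.asarray(self.gold_event))
        oe = np.atleast_1d(np.asarray(self.obs_event))
        if not (gt.size == ot.size == ge.size == oe.size):
            raise ValueError("all four columns must have equal length")
        if gt.size == 0:
            raise ValueError("no records")
        for name, arr in (("gold_time", gt), ("obs_time", ot)):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and nonnegative")
        for name, arr in (("gold_event", ge), ("obs_event", oe)):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} indicators must be 0 or 1")
        both_censored = (ge == 0) & (oe == 0)
        if np.any(both_censored & (gt != ot)):
            raise ValueError("inconsistent shared censoring: doubly censored "
                             "records must have gold_time == obs_time")
        object.__setattr__(self, "gold_time", gt)
        object.__setattr__(self, "gold_event", ge.astype(np.int8))
        object.__setattr__(self, "obs_time", ot)
        object.__setattr__(self, "obs_event", oe.astype(np.int8))

    @property
    def m(self) -> int:
        return int(self.gold_time.size)


@dataclass(frozen=True)
class MisclassParams:
    """Constant-rate misclassification parameters (theta, lambda_fp, lambda_d)."""

    theta: float
    lambda_fp: float
    lambda_d: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        for name in ("lambda_fp", "lambda_d"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = _as_float_array(grid, "grid")
    if grid.size > 1 and np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    return grid


def a_nonparametric(val: ValidationSample, grid: np.ndarray) -> np.ndarray:
    """Nonparametric estimate of a at each grid time R_k.

    a_hat(R_k) = sum_i 1{W*_i <= R_k, T*_i <= R_k} delta_i eta_i
               / sum_i 1{T*_i <= R_k} delta_i,
    set to 1 where the denominator is 0 (no gold events yet).
    """
    grid = _check_grid(grid)
    both = (val.gold_event == 1) & (val.obs_event == 1)
    # W* <= R and T* <= R  <=>  max(W*, T*) <= R
    num_key = np.sort(np.maximum(val.obs_time, val.gold_time)[both])
    den_key = np.sort(val.gold_time[val.gold_event == 1])
    num = np.searchsorted(num_key, grid, side="right").astype(float)
    den = np.searchsorted(den_key, grid, side="right").astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    return out


def b_nonparametric(val: ValidationSample, grid: np.ndarray) -> np.ndarray:
    """Nonparametric estimate of b at each grid time R_k.

    b_hat(R_k) = sum_i 1{W*_i <= R_k, T*_i > R_k} eta_i / sum_i 1{T*_i > R_k},
    set to 0 where the denominator is 0 (no subjects left event-free).
    """
    grid = _check_grid(grid)
    pos = val.obs_event == 1
    w_key = np.sort(val.obs_time[pos])
    wmax_key = np.sort(np.maximum(val.obs_time, val.gold_time)[pos])
    t_key = np.sort(val.gold_time)
    # among eta = 1: (W* <= R) minus (W* <= R and T* <= R) leaves W* <= R < T*
    num = (np.searchsorted(w_key, grid, side="right")
           - np.searchsorted(wmax_key, grid, side="right")).astype(float)
    den = (val.m - np.searchsorted(t_key, grid, side="right")).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def classify_records(val: ValidationSample, tol: float = 0.0) -> dict[str, np.ndarray]:
    """Classify each validation record by comparing (T*, delta) with (W*, eta).

    Categories (boolean masks):

    * ``on_time``       eta=1, delta=1, |W* - T*| <= tol
    * ``false_positive`` eta=1 and W* < T* - tol (early registration; includes
      false positives among subjects who never had the event), or eta=1 with
      delta=0 and W* within tol of the censoring time
    * ``late``          eta=1, delta=1, W* > T* + tol
    * ``missed``        delta=1, eta=0
    * ``nonevent``      delta=0, eta=0
    """
    gt, ge, ot, oe = val.gold_time, val.gold_event, val.obs_time, val.obs_event
    on_time = (oe == 1) & (ge == 1) & (np.abs(ot - gt) <= tol)
    early = (oe == 1) & (ot < gt - tol)
    fp_at_censor = (oe == 1) & (ge == 0) & (ot >= gt - tol)
    false_positive = early | fp_at_censor
    late = (oe == 1) & (ge == 1) & (ot > gt + tol)
    missed = (ge == 1) & (oe == 0)
    nonevent = (ge == 0) & (oe == 0)
    return {"on_time": on_time, "false_positive": false_positive, "late": late,
            "missed": missed, "nonevent": nonevent}


def estimate_params(val: ValidationSample, tol: float = 0.0) -> MisclassParams:
    """Estimate (theta, lambda_fp, lambda_d) from validation data.

    * theta: events detected at their true time / gold events not preceded by
      a false positive;
    * lambda_fp: false-positive registrations / person-time at risk of a false
      positive (0 to the earliest of the false-positive time, T*, and C —
      the risk of a false positive ends at the true event);
    * lambda_d: late detections / person-time from the true event to the
      earliest of detection and censoring, among missed or late-detected
      events.

    Each rate is 0 when its event count is 0; a positive count with zero
    person-time raises an error.
    """
    cls = classify_records(val, tol=tol)
    gt, ot = val.gold_time, val.obs_time

    gold_events = val.gold_event == 1
    fp_before_event = cls["false_positive"] & gold_events
    theta_den = int(gold_events.sum() - fp_before_event.sum())
    theta_num = int(cls["on_time"].sum())
    theta = theta_num / theta_den if theta_den > 0 else 1.0

    n_fp = int(cls["false_positive"].sum())
    fp_persontime = float(np.sum(np.where(cls["false_positive"], ot, gt)))
    lambda_fp = _safe_rate(n_fp, fp_persontime)

    n_late = int(cls["late"].sum())
    late_or_missed = cls["late"] | cls["missed"]
    d_persontime = float(np.sum((ot - gt)[late_or_missed]))
    lambda_d = _safe_rate(n_late, d_persontime)

    return MisclassParams(theta=min(theta, 1.0), lambda_fp=lambda_fp, lambda_d=lambda_d)


def _safe_rate(count: int, persontime: float) -> float:
    if count == 0:
        return 0.0
    if persontime <= 0:
        raise ValueError("degenerate validation data: events with zero person-time")
    return count / persontime


# ---------------------------------------------------------------------------
# Parametric forms
# ---------------------------------------------------------------------------

def b_parametric(params: MisclassParams, t: np.ndarray | float) -> np.ndarray | float:
    """b(t) = 1 - exp(-lambda_fp * t): exponential false-positive clock."""
    _check_nonneg(t)
    return -np.expm1(-params.lambda_fp * np.asarray(t, dtype=float))


def y_component(params: MisclassParams, t: np.ndarray | float) -> np.ndarray | float:
    """y(t) = 1 - exp(-lambda_fp * t/2): false positive before T, with the
    unknown T set midway between 0 and t."""
    _check_nonneg(t)
    return -np.expm1(-params.lambda_fp * np.asarray(t, dtype=float) / 2.0)


def x_component(params: MisclassParams, t: np.ndarray | float) -> np.ndarray | float:
    """x(t) = theta * (1 - y(t)): detection within a vanishing window of T."""
    return params.theta * (1.0 - y_component(params, t))


def z_component(params: MisclassParams, t: np.ndarray | float) -> np.ndarray | float:
    """z(t) = (1 - exp(-lambda_d * t/2)) * (1 - (y(t) + x(t))): late detection
    of a missed event, T again approximated by t/2."""
    _check_nonneg(t)
    t_arr = np.asarray(t, dtype=float)
    fd = -np.expm1(-params.lambda_d * t_arr / 2.0)
    y = y_component(params, t_arr)
    x = x_component(params, t_arr)
    return fd * (1.0 - (y + x))


def a_parametric(params: MisclassParams, t: np.ndarray | float) -> np.ndarray | float:
    """a(t) = x(t) + y(t) + z(t), clipped into [0, 1] as a floating-point guard."""
    total = (x_component(params, t) + y_component(params, t)
             + z_component(params, t))
    return np.clip(total, 0.0, 1.0)


def _check_nonneg(t) -> None:
    if np.any(np.asarray(t, dtype=float) < 0):
        raise ValueError("t must be nonnegative")


# ---------------------------------------------------------------------------
# Evaluable model wrapper
# ---------------------------------------------------------------------------

ModelKind = Literal["nonparametric", "parametric", "expert", "fixed"]


@dataclass
class MisclassModel:
    """An evaluable pair of misclassification functions a(t), b(t).

    ``a`` and ``b`` accept an array of times and return values in [0, 1].
    For the nonparametric kind the functions are step-constant on ``grid``
    (the ranked observed event times of the main study); to the left of the
    grid the denominator-zero conventions apply (a = 1, b = 0).
    """

    a: Callable[[np.ndarray], np.ndarray]
    b: Callable[[np.ndarray], np.ndarray]
    kind: ModelKind
    grid: np.ndarray | None = None
    params: MisclassParams | None = None

    @classmethod
    def from_params(cls, params: MisclassParams, kind: ModelKind = "parametric") -> "MisclassModel":
        return cls(a=lambda t: np.asarray(a_parametric(params, t), dtype=float),
                   b=lambda t: np.asarray(b_parametric(params, t), dtype=float),
                   kind=kind, params=params)

    @classmethod
    def nonparametric(cls, val: ValidationSample, grid: np.ndarray) -> "MisclassModel":
        grid = _check_grid(grid)
        a_vals = a_nonparametric(val, grid)
        b_vals = b_nonparametric(val, grid)

        def step(values: np.ndarray, left: float) -> Callable[[np.ndarray], np.ndarray]:
            def f(t: np.ndarray) -> np.ndarray:
                idx = np.searchsorted(grid, np.asarray(t, dtype=float), side="right") - 1
                return np.where(idx >= 0, values[np.clip(idx, 0, None)], left)
            return f

        return cls(a=step(a_vals, 1.0), b=step(b_vals, 0.0),
                   kind="nonparametric", grid=grid)

    @classmethod
    def fixed(cls, a: float, b: float) -> "MisclassModel":
        if not (0.0 <= b <= 1.0 and 0.0 <= a <= 1.0):
            raise ValueError("fixed a and b must lie in [0, 1]")
        return cls(a=lambda t: np.full_like(np.asarray(t, dtype=float), a),
                   b=lambda t: np.full_like(np.asarray(t, dtype=float), b),
                   kind="fixed")

    @classmethod
    def identity(cls) -> "MisclassModel":
        """Perfect measurement: a = 1, b = 0 everywhere."""
        return cls.fixed(1.0, 0.0)
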