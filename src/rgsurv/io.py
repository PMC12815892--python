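"""CSV input/output for survival and validation data.

Dialect: comma-separated, UTF-8, header required, ``.`` decimal.  Times are
in user units (the tool is unit-agnostic; the horizon must be supplied in
the same unit).  Main-study files carry columns ``time`` and ``event``
(optional ``id``); validation files carry ``gold_time``, ``gold_event``,
``obs_time``, ``obs_event`` (optional ``id``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Union

import numpy as np
import pandas as pd

from .misclassification import ValidationSample
from .risk import RiskCurve, SurvivalSample
from .uncertainty import UncertaintyResult

__all__ = ["read_survival_csv", "write_risk_csv"]

MAIN_COLUMNS = ("time", "event")
VALIDATION_COLUMNS = ("gold_time", "gold_event", "obs_time", "obs_event")


def _report_bad_rows(mask: np.ndarray, message: str, errors: list[str]) -> None:
    if mask.any():
        # +2: one for the header line, one for 0-based indexing
        lines = ", ".join(str(i + 2) for i in np.flatnonzero(mask)[:20])
        errors.append(f"{message} (line{'s' if mask.sum() > 1 else ''} {lines})")


def read_survival_csv(path: Union[str, Path],
                      schema: Literal["main", "validation"] = "main"
                      ) -> SurvivalSample | ValidationSample:
    """Read and validate a main-study or validation CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no records") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no records")
    required = MAIN_COLUMNS if schema == "main" else VALIDATION_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")

    errors: list[str] = []
    for col in required:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        _report_bad_rows(np.isnan(vals), f"non-numeric {col}", errors)
        df[col] = vals
    if not errors:
        time_cols = [c for c in required if c.endswith("time")]
        event_cols = [c for c in required if c.endswith("event")]
        for col in time_cols:
            _report_bad_rows(df[col].to_numpy() < 0, f"negative {col}", errors)
        for col in event_cols:
            _report_bad_rows(~np.isin(df[col].to_numpy(), (0.0, 1.0)),
                             f"non-binary {col}", errors)
    if not errors and schema == "validation":
        both_cens = (df["gold_event"] == 0) & (df["obs_event"] == 0)
        mismatch = both_cens & (df["gold_time"] != df["obs_time"])
        _report_bad_rows(mismatch.to_numpy(),
                         "inconsistent shared censoring", errors)
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))

    if schema == "main":
        return SurvivalSample(time=df["time"].to_numpy(),
                              event=df["event"].to_numpy().astype(int))
    return ValidationSample(gold_time=df["gold_time"].to_numpy(),
                            gold_event=df["gold_event"].to_numpy().astype(int),
                            obs_time=df["obs_time"].to_numpy(),
                            obs_event=df["obs_event"].to_numpy().astype(int))


def write_risk_csv(result: Union[UncertaintyResult, RiskCurve],
                   path: Union[str, Path]) -> None:
    """Write a risk curve (with uncertainty, if available) as tidy CSV.

    Columns: time, risk, se, ci_lower, ci_upper, method; a t = 0 anchor row
    (risk 0) precedes the jump grid.  Floats are written with 12 significant
    digits so a read-back reproduces the curve to that precision.
    """
    if isinstance(result, UncertaintyResult):
        curve = result.point
        se, lo, hi = result.se, result.ci_lower, result.ci_upper
        method = result.method
    else:
        curve = result
        se = curve.se if curve.se is not None else np.full(curve.grid.size, np.nan)
        if curve.se is not None:
            lo = np.clip(curve.values - 1.96 * se, 0.0, 1.0)
            hi = np.clip(curve.values + 1.96 * se, 0.0, 1.0)
        else:
            lo = hi = np.full(curve.grid.size, np.nan)
        method = curve.meta.get("estimator", "risk_curve")
    df = pd.DataFrame({
        "time": np.concatenate(([0.0], curve.grid)),
        "risk": np.concatenate(([0.0], curve.values)),
        "se": np.concatenate(([0.0 if curve.grid.size else np.nan], se)),
        "ci_lower": np.concatenate(([np.nan], lo)),
        "ci_upper": np.concatenate(([np.nan], hi)),
        "method": method,
    })
    df.to_csv(path, index=False, float_format="%.12g")
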