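"""Scoring forecasts against held-out rates: RMSE and Spearman correlation.

RMSE measures absolute per-county error in rate units; the Spearman rank
correlation measures whether a forecaster orders counties correctly — the
quantity that matters when predictions guide resource allocation even if
their level is biased. Ties receive mid-ranks. A constant prediction vector
has no defined rank correlation and raises rather than silently scoring 0,
since a constant forecaster is almost always a pipeline bug.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedMetricError, ValidationError
from .forecasters import ForecastResult

__all__ = ["rmse", "spearman", "evaluate_models", "comparison_table"]


def _aligned(pred, actual) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise ValidationError(f"misaligned vectors: {p.shape} vs {a.shape}")
    return p, a


def rmse(pred, actual) -> float:
    """Root mean squared error, in the units of the rates."""
    p, a = _aligned(pred, actual)
    if p.size == 0:
        raise ValidationError("empty vectors")
    return float(np.sqrt(np.mean((p - a) ** 2)))


def spearman(pred, actual) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    p, a = _aligned(pred, actual)
    if p.size < 2:
        raise ValidationError("need n >= 2 for a correlation")
    if np.unique(p).size == 1 or np.unique(a).size == 1:
        raise UndefinedMetricError("zero rank variance: correlation undefined")
    return float(stats.spearmanr(p, a).statistic)


def evaluate_models(
    forecasts: ForecastResult,
    actual,
    sort_by: str = "rmse",
) -> pd.DataFrame:
    """Table-style report: one row per model with RMSE and Spearman.

    Models with missing predictions are excluded (their failure is already
    recorded on the ForecastResult). ``sort_by`` is ``"rmse"`` (ascending)
    or ``"name"`` for fixed model order.
    """
    _, a = _aligned(forecasts.table[forecasts.models[0]].to_numpy(), actual)
    rows = []
    for name in forecasts.models:
        p = forecasts.table[name].to_numpy(dtype=float)
        if np.isnan(p).any():
            continue
        rows.append(
            {"model": name, "rmse": rmse(p, a), "spearman": spearman(p, a),
             "n": p.size}
        )
    if not rows:
        raise ValidationError("no scorable models")
    report = pd.DataFrame(rows)
    if sort_by == "rmse":
        report = report.sort_values("rmse", kind="stable", ignore_index=True)
    elif sort_by != "name":
        raise ValidationError(f"unknown sort_by {sort_by!r}")
    return report


def comparison_table(
    forecasts: ForecastResult,
    actual,
    sort_by_actual: bool = False,
) -> pd.DataFrame:
    """Tidy long table (county, fips, actual, model, predicted) for plotting."""
    a = np.asarray(actual, dtype=float)
    if a.shape != (len(forecasts.table),):
        raise ValidationError("actual length must match forecast table")
    wide = forecasts.table.copy()
    wide.insert(1, "actual", a)
    wide.insert(0, "county_index", np.arange(len(wide)))
    long = wide.melt(
        id_vars=["county_index", "fips", "actual"],
        var_name="model", value_name="predicted",
    )
    if sort_by_actual:
        long = long.sort_values(
            ["actual", "model", "fips"], kind="stable", ignore_index=True
        )
    return long
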