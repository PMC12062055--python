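"""Comparator forecasting models behind one common one-step contract.

Five baselines accompany the decomposition: Holt exponential smoothing with
trend (applied county-by-county), lagged linear regression, random forest,
gradient boosting, and RBF-kernel support-vector regression. The supervised
models share one framing: counties are rows, the L prior years are the
feature columns, and the following year is the target (:class:`LagDesign`).
A model tuned on features y_0..y_{L-1} -> target y_L is applied to the
window shifted one year forward to forecast the held-out year.

Hyperparameters for the tree/kernel models are chosen by exhaustive grid
search scored on training-set RMSE (not cross-validation); the grid table is
returned so the selection is auditable, and ties go to the first cell in
enumeration order. SVR features are standardized (zero mean, unit variance)
so absolute gamma values are meaningful.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import InsufficientDataError, ValidationError
from .io_panel import IncidencePanel

__all__ = [
    "LagDesign",
    "GridSearchSpec",
    "FittedRegressor",
    "LinregResult",
    "ForecastResult",
    "make_lag_design",
    "holt_forecast",
    "linreg_fit",
    "linreg_predict",
    "fit_ml_regressor",
    "forecast_all",
    "default_grid",
    "ML_FAMILIES",
    "ALL_MODELS",
]

ML_FAMILIES = ("random_forest", "gradient_boosting", "svm_rbf")
ALL_MODELS = ("dmd", "holt", "linreg") + ML_FAMILIES


@dataclass
class LagDesign:
    """Supervised framing of a panel: counties x lag-window features."""

    features: np.ndarray = field(repr=False)  # (n, L)
    target: np.ndarray = field(repr=False)  # (n,)
    lag: int
    counties: list[str]
    feature_years: list[int]
    target_year: int


@dataclass(frozen=True)
class GridSearchSpec:
    """Exhaustive hyperparameter grid; Cartesian product in insertion order."""

    param_grid: dict[str, tuple]

    def __post_init__(self):
        if not self.param_grid or any(len(v) == 0 for v in self.param_grid.values()):
            raise ValidationError("every grid dimension must be non-empty")

    def cells(self) -> list[dict]:
        names = list(self.param_grid)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.param_grid[k] for k in names))
        ]


@dataclass
class FittedRegressor:
    """Grid-search outcome: refit estimator plus the full scored grid."""

    family: str
    estimator: object
    best_params: dict
    grid_table: pd.DataFrame  # one row per cell, with training RMSE

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(features), dtype=float)


@dataclass
class LinregResult:
    """OLS fit: intercept followed by L lag weights; min-norm if deficient."""

    coefficients: np.ndarray  # (L + 1,)
    rank: int
    rank_deficient: bool


@dataclass
class ForecastResult:
    """Aligned per-county forecasts for one target year, one column per model."""

    table: pd.DataFrame  # columns: fips, <model>...
    target_year: int
    errors: dict[str, str]  # model -> failure message, for models that failed

    @property
    def models(self) -> list[str]:
        return [c for c in self.table.columns if c != "fips"]


def make_lag_design(
    panel: IncidencePanel,
    feature_years: tuple[int, int],
    target_year: int,
) -> LagDesign:
    """Features = each county's rates over ``feature_years``; target = next year.

    ``target_year`` must immediately follow the last feature year so the lag
    structure is a true one-step-ahead design.
    """
    first, last = feature_years
    if target_year != last + 1:
        raise ValidationError(
            f"target year {target_year} must be last feature year {last} + 1"
        )
    sub = panel.restrict_years(first, last)
    return LagDesign(
        features=sub.values.copy(),
        target=panel.column(target_year),
        lag=sub.n_years,
        counties=list(panel.counties),
        feature_years=list(sub.years),
        target_year=target_year,
    )


def holt_forecast(series: np.ndarray, alpha: float = 0.2, beta: float = 0.1) -> float:
    """One-step-ahead Holt (exponential smoothing with additive trend).

    Level/trend recursions, initialized l_1 = y_1, b_1 = y_2 - y_1 and run
    for t = 2..m::

        l_t = alpha * y_t + (1 - alpha) * (l_{t-1} + b_{t-1})
        b_t = beta * (l_t - l_{t-1}) + (1 - beta) * b_{t-1}

    The forecast is l_m + b_m. ``alpha`` weights recent observations in the
    level; the default 0.2 follows common practice for slowly-trending
    public-health rate series. ``beta`` smooths the trend estimate.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise InsufficientDataError("Holt needs a 1-D series of length >= 2")
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ValidationError("alpha and beta must lie in (0, 1)")
    level, trend = y[0], y[1] - y[0]
    for t in range(1, y.size):
        prev = level
        level = alpha * y[t] + (1 - alpha) * (level + trend)
        trend = beta * (level - prev) + (1 - beta) * trend
    return float(level + trend)


def _holt_insample_sse(y: np.ndarray, alpha: float, beta: float) -> float:
    """Sum of squared one-step errors of the Holt recursion over t = 2..m."""
    level, trend = y[0], y[1] - y[0]
    sse = 0.0
    for t in range(1, y.size):
        sse += (level + trend - y[t]) ** 2
        prev = level
        level = alpha * y[t] + (1 - alpha) * (level + trend)
        trend = beta * (level - prev) + (1 - beta) * trend
    return sse


def holt_forecast_optimized_beta(
    series: np.ndarray, alpha: float = 0.2, beta_grid: np.ndarray | None = None
) -> tuple[float, float]:
    """Holt forecast with beta chosen by in-sample one-step SSE on a grid.

    Returns (forecast, chosen beta); ties go to the smaller beta.
    """
    y = np.asarray(series, dtype=float)
    if beta_grid is None:
        beta_grid = np.linspace(0.05, 0.95, 20)
    sses = [_holt_insample_sse(y, alpha, b) for b in beta_grid]
    best = float(beta_grid[int(np.argmin(sses))])
    return holt_forecast(y, alpha, best), best


def linreg_fit(design: LagDesign) -> LinregResult:
    """Ordinary least squares of target on [1, features].

    Rank-deficient designs get the minimum-norm solution and are flagged.
    """
    X = np.column_stack([np.ones(len(design.target)), design.features])
    coef, _, rank, _ = np.linalg.lstsq(X, design.target, rcond=None)
    return LinregResult(
        coefficients=coef, rank=int(rank),
        rank_deficient=rank < X.shape[1],
    )


def linreg_predict(result: LinregResult, features: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(features.shape[0]), features])
    return X @ result.coefficients


def default_grid(family: str) -> GridSearchSpec:
    """Conventional grids. The SVR cost/gamma grid is the canonical 4 x 4."""
    if family == "random_forest":
        return GridSearchSpec({"n_estimators": (100, 300, 500), "max_depth": (3, 5, 10)})
    if family == "gradient_boosting":
        # interaction depth of the boosted trees maps to max_depth
        return GridSearchSpec({"n_estimators": (100, 300, 500), "max_depth": (1, 3, 5)})
    if family == "svm_rbf":
        return GridSearchSpec({"C": (0.1, 1, 10, 100), "gamma": (0.1, 1, 10, 100)})
    raise ValidationError(f"unknown model family {family!r}")


def _build_estimator(family: str, params: dict, seed: int):
    if family == "random_forest":
        return RandomForestRegressor(random_state=seed, **params)
    if family == "gradient_boosting":
        return GradientBoostingRegressor(random_state=seed, **params)
    if family == "svm_rbf":
        return Pipeline(
            [("scale", StandardScaler()), ("svr", SVR(kernel="rbf", **params))]
        )
    raise ValidationError(f"unknown model family {family!r}")


def fit_ml_regressor(
    design: LagDesign,
    family: str,
    grid: GridSearchSpec | None = None,
    seed: int = 0,
) -> FittedRegressor:
    """Exhaustive grid search scored by training RMSE, then refit at the best cell.

    Every cell is fitted on the full design and scored on the same rows
    (training RMSE); the lowest-RMSE cell wins, ties broken by enumeration
    order. Deterministic given ``seed``.
    """
    if family not in ML_FAMILIES:
        raise ValidationError(
            f"unknown model family {family!r}; expected one of {ML_FAMILIES}"
        )
    grid = grid or default_grid(family)
    rows = []
    best_rmse, best_params = np.inf, None
    for params in grid.cells():
        est = _build_estimator(family, params, seed)
        est.fit(design.features, design.target)
        resid = est.predict(design.features) - design.target
        rmse = float(np.sqrt(np.mean(resid**2)))
        rows.append({**params, "train_rmse": rmse})
        if rmse < best_rmse:  # strict: first of any tie wins
            best_rmse, best_params = rmse, params
    final = _build_estimator(family, best_params, seed)
    final.fit(design.features, design.target)
    return FittedRegressor(
        family=family, estimator=final, best_params=best_params,
        grid_table=pd.DataFrame(rows),
    )


def forecast_all(
    panel: IncidencePanel,
    train_window: tuple[int, int],
    target_year: int,
    models: tuple[str, ...] = ALL_MODELS,
    dmd_rank: int | str = "full",
    holt_alpha: float = 0.2,
    holt_beta: float = 0.1,
    grids: dict[str, GridSearchSpec] | None = None,
    seed: int = 0,
) -> ForecastResult:
    """Per-county one-step forecasts of ``target_year`` from every model.

    The supervised models are tuned on the design (train_window[0] ..
    train_window[1] - 1) -> train_window[1], then applied to the window
    shifted forward one year. DMD and Holt consume the whole training
    window directly. Individual model failures are recorded without
    aborting the rest.
    """
    from . import dmd as _dmd  # local import avoids a cycle at package init

    first, last = train_window
    if target_year != last + 1:
        raise ValidationError(
            f"target year {target_year} must be train-window end {last} + 1"
        )
    unknown = set(models) - set(ALL_MODELS)
    if unknown:
        raise ValidationError(f"unknown models {sorted(unknown)}")

    train = panel.restrict_years(first, last)
    out = pd.DataFrame({"fips": train.counties})
    errors: dict[str, str] = {}

    fit_design = pred_features = None
    if any(m in models for m in ("linreg",) + ML_FAMILIES):
        fit_design = make_lag_design(panel, (first, last - 1), last)
        pred_features = panel.restrict_years(first + 1, last).values

    for name in models:
        try:
            if name == "dmd":
                snaps = _dmd.build_snapshots(train)
                model = _dmd.fit(snaps, dmd_rank)
                pred = _dmd.predict(model, snaps.m + 1)
            elif name == "holt":
                pred = np.array(
                    [holt_forecast(row, holt_alpha, holt_beta) for row in train.values]
                )
            elif name == "linreg":
                pred = linreg_predict(linreg_fit(fit_design), pred_features)
            else:
                grid = (grids or {}).get(name)
                reg = fit_ml_regressor(fit_design, name, grid, seed=seed)
                pred = reg.predict(pred_features)
            if not np.all(np.isfinite(pred)):
                raise ValidationError("non-finite predictions")
            out[name] = pred
        except Exception as exc:  # per-model isolation by contract
            errors[name] = f"{type(exc).__name__}: {exc}"
    if len(out.columns) == 1:
        raise ValidationError(f"every model failed: {errors}")
    return ForecastResult(table=out, target_year=target_year, errors=errors)
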