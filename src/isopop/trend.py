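"""Ordinary least-squares trend of diversity metrics across sampling periods.

The periods are equally spaced 5-year windows, so the regressor defaults
to the period index 1..k; slopes are then in metric units per period.
With only k = 5 points the model is the textbook simple regression, and
the p-value comes from the F distribution with (1, k-2) degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TrendResult", "ols_trend", "trend_suite"]


@dataclass
class TrendResult:
    metric: str
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    F: float
    R2: float
    p_value: float
    k: int

    def to_dict(self):
        return dict(metric=self.metric, slope=self.slope, slope_se=self.slope_se,
                    intercept=self.intercept, intercept_se=self.intercept_se,
                    F=self.F, R2=self.R2, p_value=self.p_value, k=self.k)


def ols_trend(y: Sequence[float], x: Optional[Sequence[float]] = None,
              x_coding: str = "index", metric: str = "metric") -> TrendResult:
    """Simple linear regression of a per-period metric.

    ``x_coding='index'`` regresses on 1..k (the default; slopes are per
    period); ``'midyear'`` requires explicit ``x`` values (e.g. period
    midpoint years).  Requires k >= 3 distinct-x points.
    """
    y = np.asarray(y, dtype=float)
    k = len(y)
    if k < 3:
        raise ValueError("need at least 3 periods for a trend regression")
    if np.any(np.isnan(y)):
        raise ValueError("metric series contains missing values")
    if x is None:
        if x_coding == "index":
            x = np.arange(1, k + 1, dtype=float)
        else:
            raise ValueError("x values required for non-index coding")
    x = np.asarray(x, dtype=float)
    if len(x) != k:
        raise ValueError("x and y lengths differ")
    if np.ptp(x) == 0:
        raise ValueError("constant regressor")

    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    syy = float(np.sum((y - ybar) ** 2))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid ** 2))
    df = k - 2
    mse = sse / df
    slope_se = np.sqrt(mse / sxx)
    intercept_se = np.sqrt(mse * (1.0 / k + xbar ** 2 / sxx))
    ssr = slope * sxy
    if syy == 0.0:
        r2, F, p = 0.0, 0.0, 1.0
    else:
        r2 = ssr / syy
        F = ssr / mse if mse > 0 else np.inf
        p = float(stats.f.sf(F, 1, df)) if np.isfinite(F) else 0.0
    return TrendResult(metric=metric, slope=slope, slope_se=float(slope_se),
                       intercept=intercept, intercept_se=float(intercept_se),
                       F=float(F), R2=float(r2), p_value=p, k=k)


def trend_suite(summary: pd.DataFrame, metrics=("Na", "Ho", "Fis"),
                fis_column: str = "Fis_wc") -> dict:
    """Trend regressions of period-average Na, Ho and F_IS.

    ``summary`` is a :func:`isopop.diversity.diversity_table` frame (or any
    frame with a ``locus == 'Average'`` row per period).  Returns
    ``{metric: TrendResult}``; a metric whose period averages contain NaN
    is omitted with a warning.
    """
    import warnings

    avg = summary[summary["locus"] == "Average"]
    if len(avg) < 3:
        raise ValueError("need at least 3 periods with average rows")
    out = {}
    for metric in metrics:
        col = fis_column if metric == "Fis" else metric
        ys = avg[col].to_numpy(dtype=float)
        if np.any(np.isnan(ys)):
            warnings.warn(f"metric {metric}: undefined period average; row omitted")
            continue
        out[metric] = ols_trend(ys, metric=metric)
    return out


def trend_frame(results: dict) -> pd.DataFrame:
    """Flatten a trend_suite result into a tidy table."""
    return pd.DataFrame([r.to_dict() for r in results.values()])
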