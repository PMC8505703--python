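"""Temporal characterization of an index series.

The index is expected to show a plateau (roughly constant level) followed by
a near-linear decline. This module quantifies that behavior:

* :func:`rolling_mean` — centered moving average (default 7 days, the weekly
  posting cycle).
* :func:`fit_linear_trend` — ordinary least squares of I(d) on integer day
  offset within a window, with a 95% confidence interval on the slope. The
  normal equations are written out here so the fit is self-contained and can
  be cross-checked against a matrix-algebra oracle.
* :func:`range_check` — extrema and the fraction of days inside a stated
  band (plateau check).
* :func:`compare_windows` — difference of window means with a seeded
  permutation test.
* :func:`align_and_correlate` — Pearson correlation against an external
  daily series (deaths, vaccination share) after date intersection and an
  optional lag.

Missing days (T = 0, NaN index) are dropped from every computation, never
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .daily_index import IndexSeries

__all__ = [
    "TrendFit",
    "RangeCheck",
    "WindowComparison",
    "CorrelationResult",
    "ExternalSeries",
    "read_external_series",
    "rolling_mean",
    "fit_linear_trend",
    "range_check",
    "compare_windows",
    "align_and_correlate",
]

# cumulative external series (vaccination share) may be weekly; fill at most
_MAX_FFILL_DAYS = 6


@dataclass(frozen=True)
class TrendFit:
    """OLS line through I(d) over a date window.

    ``slope`` is in index units per day; ``intercept`` is the fitted index at
    the window's first day (x = 0 there).
    """

    window: tuple[date, date]
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    slope_ci95: tuple[float, float]
    n_days: int

    def predict(self, day: date) -> float:
        return self.intercept + self.slope * (day - self.window[0]).days


@dataclass(frozen=True)
class RangeCheck:
    window: tuple[date, date]
    min_index: float
    max_index: float
    band: tuple[float, float] | None
    fraction_in_band: float | None
    n_days: int


@dataclass(frozen=True)
class WindowComparison:
    mean_a: float
    mean_b: float
    difference: float
    p_value: float
    n_permutations: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    lag_days: int
    label: str


@dataclass(frozen=True)
class ExternalSeries:
    """Daily (date, value) series, e.g. deaths per day or share vaccinated."""

    values: pd.Series  # DatetimeIndex -> float
    label: str

    def __post_init__(self) -> None:
        idx = self.values.index
        if len(idx) and not idx.is_monotonic_increasing:
            raise ValueError("external series dates must be increasing")
        if idx.has_duplicates:
            raise ValueError("external series dates must be unique")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("external series values must be finite")

    def forward_filled(self, max_days: int = _MAX_FFILL_DAYS) -> "ExternalSeries":
        """Daily reindex with forward fill limited to ``max_days``.

        Meant for cumulative, sparsely reported quantities (vaccination
        share). Incidence series such as daily deaths should not be filled.
        """
        full = pd.date_range(self.values.index[0], self.values.index[-1], freq="D")
        filled = self.values.reindex(full).ffill(limit=max_days).dropna()
        return ExternalSeries(values=filled, label=self.label)


def read_external_series(path: str | Path, label: str | None = None) -> ExternalSeries:
    """Read a 2-column CSV ``date,value`` with a header row."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (date,value)")
    dates = pd.to_datetime(frame.iloc[:, 0])
    values = pd.Series(frame.iloc[:, 1].to_numpy(dtype=float), index=pd.DatetimeIndex(dates))
    values = values.sort_index()
    return ExternalSeries(values=values, label=label or str(frame.columns[1]))


def _window_index(series: IndexSeries, window: tuple[date, date] | None) -> pd.Series:
    if window is None:
        vals = series.index_values
    else:
        start, end = window
        if start > end:
            raise ValueError("window start after end")
        vals = series.subset(start, end).index_values
    return vals


def rolling_mean(series: IndexSeries, window_days: int = 7) -> pd.Series:
    """Centered moving average of I(d); endpoints use shrunken windows.

    ``window_days`` must be odd and at least 1, and no larger than the
    series. Missing days stay missing and do not contribute to neighbors.
    """
    if window_days < 1 or window_days % 2 == 0:
        raise ValueError("window_days must be odd and >= 1")
    if window_days > len(series):
        raise ValueError("smoothing window larger than the series")
    return series.index_values.rolling(window_days, center=True, min_periods=1).mean()


def fit_linear_trend(series: IndexSeries, window: tuple[date, date] | None = None) -> TrendFit:
    """OLS of I(d) on day offset from the window start, with 95% CI on slope.

    Requires at least 3 non-missing days in the window; missing days are
    dropped. The confidence interval uses the slope's standard error and a
    Student-t critical value with n - 2 degrees of freedom.
    """
    vals = _window_index(series, window)
    mask = vals.notna()
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"linear trend needs >= 3 non-missing days, got {n}")
    if window is None:
        start = vals.index[0].date()
        end = vals.index[-1].date()
    else:
        start, end = window
    x = np.array([(ts.date() - start).days for ts in vals.index[mask]], dtype=float)
    y = vals.to_numpy(dtype=float)[mask.to_numpy()]

    # closed-form normal equations
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    ssr = float((resid**2).sum())
    sst = float(((y - ybar) ** 2).sum())
    r_squared = 1.0 if sst == 0.0 else max(0.0, 1.0 - ssr / sst)
    sigma2 = ssr / (n - 2) if n > 2 else 0.0
    stderr = float(np.sqrt(sigma2 / sxx))
    tcrit = float(sp_stats.t.ppf(0.975, n - 2))
    ci = (slope - tcrit * stderr, slope + tcrit * stderr)
    return TrendFit(
        window=(start, end),
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        slope_stderr=stderr,
        slope_ci95=ci,
        n_days=n,
    )


def range_check(
    series: IndexSeries,
    window: tuple[date, date] | None = None,
    band: tuple[float, float] | None = None,
) -> RangeCheck:
    """Extrema of I(d) in a window, plus the fraction of days inside ``band``."""
    vals = _window_index(series, window)
    clean = vals.dropna()
    if clean.empty:
        raise ValueError("range_check window contains no non-missing days")
    frac = None
    if band is not None:
        lo, hi = band
        if lo > hi:
            raise ValueError("band lower bound above upper bound")
        frac = float(((clean >= lo) & (clean <= hi)).mean())
    start = window[0] if window else vals.index[0].date()
    end = window[1] if window else vals.index[-1].date()
    return RangeCheck(
        window=(start, end),
        min_index=float(clean.min()),
        max_index=float(clean.max()),
        band=band,
        fraction_in_band=frac,
        n_days=int(clean.size),
    )


def compare_windows(
    series: IndexSeries,
    window_a: tuple[date, date],
    window_b: tuple[date, date],
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> WindowComparison:
    """Difference of window means with a seeded label-permutation test.

    Windows must be disjoint with at least 3 non-missing days each. The
    two-sided p-value counts permutations whose absolute mean difference is
    at least the observed one, with the +1 correction so p is never 0.
    """
    if not (window_a[1] < window_b[0] or window_b[1] < window_a[0]):
        raise ValueError("comparison windows must be disjoint")
    a = _window_index(series, window_a).dropna().to_numpy(dtype=float)
    b = _window_index(series, window_b).dropna().to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each window needs >= 3 non-missing days")
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_a = len(a)
    # vectorized permutations: each row is one shuffled pooled sample
    perm = rng.permuted(np.tile(pooled, (n_permutations, 1)), axis=1)
    diffs = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
    p = (1 + int((np.abs(diffs) >= abs(observed) - 1e-15).sum())) / (n_permutations + 1)
    return WindowComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=float(observed),
        p_value=float(p),
        n_permutations=n_permutations,
    )


def align_and_correlate(
    series: IndexSeries, external: ExternalSeries, lag_days: int = 0
) -> CorrelationResult:
    """Pearson r between I(d) and an external series on date-matched pairs.

    A positive ``lag_days`` compares I(d) with the external value at
    d - lag (the external series leads). Needs at least 3 overlapping
    non-missing dates after the shift.
    """
    ext = external.values.copy()
    ext.index = ext.index + timedelta(days=lag_days)
    joined = pd.concat([series.index_values.rename("i"), ext.rename("x")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(
            f"only {len(joined)} overlapping dates after lag {lag_days}; need >= 3"
        )
    r = float(sp_stats.pearsonr(joined["i"], joined["x"]).statistic)
    return CorrelationResult(r=r, n=int(len(joined)), lag_days=lag_days, label=external.label)
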