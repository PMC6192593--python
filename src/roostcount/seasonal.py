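"""Seasonal-trend decomposition of monthly count series via loess.

A monthly series is split additively into a 12-periodic seasonal component,
a smooth long-term trend, and a remainder:

    y(t) = seasonal(month(t)) + trend(t) + remainder(t)

The fit alternates two steps: (1) the seasonal component is the month-wise
mean of the detrended series (the "subseries" means), centred to sum to
zero over the twelve months; (2) the trend is a locally weighted linear
regression (loess, tricube weights) of the deseasonalised series on time.
A couple of passes stabilise both components.  Seasonal components are
summarised as range-standardised profiles on [0, 1] for comparison across
roosts and flock-size strata.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import STRATA, CountTable
from .exceptions import CoverageError, DegenerateProfileError

#: Neighbourhood size of the trend loess, matching the conventional trend
#: window for a period-12 series with a strictly periodic seasonal.
TREND_WINDOW = 19


@dataclass(frozen=True)
class MonthlySeries:
    """One roost x stratum monthly series on a contiguous calendar grid.

    ``values[i]`` belongs to calendar position i months after
    ``start = (year, month)``; gaps are ``NaN``, never skipped.
    """

    roost_id: str
    stratum: str
    start: tuple[int, int]
    values: np.ndarray
    period: int = 12

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)

    def calendar(self) -> list[tuple[int, int]]:
        y0, m0 = self.start
        out = []
        for i in range(len(self.values)):
            k = (m0 - 1) + i
            out.append((y0 + k // 12, k % 12 + 1))
        return out

    def months(self) -> np.ndarray:
        """Calendar month (1-12) at each position."""
        m0 = self.start[1]
        return (np.arange(len(self.values)) + m0 - 1) % 12 + 1

    @classmethod
    def from_table(cls, table: CountTable, roost: str, stratum: str) -> "MonthlySeries":
        if stratum not in STRATA:
            raise ValueError(f"unknown stratum {stratum!r}")
        sub = table.df[table.df["roost"] == str(roost)]
        if sub.empty:
            raise KeyError(f"no records for roost {roost!r}")
        y0, m0 = int(sub.iloc[0]["year"]), int(sub.iloc[0]["month"])
        idx = (sub["year"] - y0) * 12 + (sub["month"] - m0)
        n = int(idx.max()) + 1
        vals = np.full(n, np.nan)
        vals[idx.to_numpy(dtype=int)] = sub[stratum].to_numpy(dtype=float)
        return cls(roost_id=str(roost), stratum=stratum, start=(y0, m0), values=vals)


@dataclass(frozen=True)
class STLDecomposition:
    """Additive seasonal / trend / remainder split of one monthly series."""

    series: MonthlySeries
    seasonal: np.ndarray
    trend: np.ndarray
    remainder: np.ndarray
    interpolated: np.ndarray  # True where the input was filled before fitting
    span: float
    n_iter: int

    @property
    def seasonal_by_month(self) -> np.ndarray:
        """The twelve seasonal values indexed by calendar month 1-12."""
        months = self.series.months()
        out = np.empty(12)
        for m in range(1, 13):
            out[m - 1] = self.seasonal[months == m][0]
        return out

    def to_frame(self) -> pd.DataFrame:
        cal = self.series.calendar()
        return pd.DataFrame(
            {
                "year": [y for y, _ in cal],
                "month": [m for _, m in cal],
                "observed": self.series.values,
                "seasonal": self.seasonal,
                "trend": self.trend,
                "remainder": self.remainder,
                "interpolated": self.interpolated,
            }
        )


def loess_smooth(
    t: np.ndarray, y: np.ndarray, span: float, degree: int = 1
) -> np.ndarray:
    """Locally weighted polynomial smoothing with tricube weights.

    At each target point the q = ceil(span * n) nearest neighbours get
    weights w = (1 - (d / d_max)^3)^3 and a degree-0 or degree-1 weighted
    polynomial is fitted and evaluated at the target.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree not in (0, 1):
        raise ValueError("degree must be 0 or 1")
    n = len(t)
    if n != len(y):
        raise ValueError("t and y must have equal length")
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    q = math.ceil(span * n)
    if q < degree + 1:
        raise ValueError(f"span {span} gives {q} neighbours; need >= {degree + 1}")
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(t - t[i])
        neighbours = np.argsort(d, kind="stable")[:q]
        dmax = d[neighbours].max()
        if dmax == 0:
            fitted[i] = y[neighbours].mean()
            continue
        w = (1 - (d[neighbours] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        tw, yw = t[neighbours], y[neighbours]
        if degree == 0:
            fitted[i] = np.sum(w * yw) / np.sum(w)
        else:
            # weighted straight-line fit, evaluated at t[i]
            sw = np.sum(w)
            tbar = np.sum(w * tw) / sw
            ybar = np.sum(w * yw) / sw
            sxx = np.sum(w * (tw - tbar) ** 2)
            if sxx == 0:
                fitted[i] = ybar
            else:
                slope = np.sum(w * (tw - tbar) * (yw - ybar)) / sxx
                fitted[i] = ybar + slope * (t[i] - tbar)
    return fitted


def seasonal_subseries_means(values: np.ndarray, months: np.ndarray) -> np.ndarray:
    """Month-wise means of a (detrended) series, centred to zero sum.

    Returns the twelve values indexed by calendar month 1-12.  Every month
    must be represented by at least one non-missing value.
    """
    values = np.asarray(values, dtype=float)
    months = np.asarray(months, dtype=int)
    out = np.empty(12)
    for m in range(1, 13):
        v = values[(months == m) & ~np.isnan(values)]
        if v.size == 0:
            raise CoverageError(f"no observations in calendar month {m}")
        out[m - 1] = v.mean()
    return out - out.mean()


def _interpolate_internal(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, slice]:
    """Fill internal gaps linearly; trim leading/trailing gaps.

    Returns (filled values, interpolated mask, slice into the original array).
    """
    isnan = np.isnan(values)
    if isnan.all():
        raise ValueError("series is entirely missing")
    first = int(np.argmax(~isnan))
    last = len(values) - int(np.argmax(~isnan[::-1]))
    window = slice(first, last)
    v = values[window].copy()
    mask = np.isnan(v)
    if mask.any():
        idx = np.arange(len(v))
        v[mask] = np.interp(idx[mask], idx[~mask], v[~mask])
    return v, mask, window


def stl_decompose(
    series: MonthlySeries,
    span: float | None = None,
    n_iter: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> STLDecomposition:
    """Three-step additive decomposition of a monthly series.

    Iterates: detrend, take centred month-wise subseries means as the
    seasonal, deseasonalise, re-estimate the trend by degree-1 loess.  The
    alternation is a linear contraction; by default it runs until the trend
    stabilises (relative change below ``tol``), which removes the leakage of
    a linear trend into the month-wise means.  Pass ``n_iter`` to force a
    fixed number of passes instead.  The remainder is the residual from
    seasonal + trend; at internally interpolated months it is reported
    missing.  Leading/trailing missing months are trimmed, never
    extrapolated.
    """
    values = np.asarray(series.values, dtype=float)
    v, interp_mask, window = _interpolate_internal(values)
    if window.start > 0 or window.stop < len(values):
        y0, m0 = series.start
        k = (m0 - 1) + window.start
        series = MonthlySeries(
            roost_id=series.roost_id,
            stratum=series.stratum,
            start=(y0 + k // 12, k % 12 + 1),
            values=values[window],
        )
    if len(v) < 24:
        raise ValueError(
            f"decomposition requires >= 24 monthly observations, got {len(v)}"
        )
    months = series.months()
    if span is None:
        span = min(1.0, TREND_WINDOW / len(v))
    t = np.arange(len(v), dtype=float)
    trend = np.full(len(v), v.mean())
    seasonal = np.zeros(len(v))
    limit = max_iter if n_iter is None else max(1, int(n_iter))
    scale = max(1.0, float(np.nanmax(np.abs(v))))
    iterations = 0
    for _ in range(limit):
        by_month = seasonal_subseries_means(v - trend, months)
        seasonal = by_month[months - 1]
        new_trend = loess_smooth(t, v - seasonal, span=span, degree=1)
        delta = float(np.max(np.abs(new_trend - trend)))
        trend = new_trend
        iterations += 1
        if n_iter is None and delta < tol * scale:
            break
    remainder = v - seasonal - trend
    remainder = remainder.copy()
    remainder[interp_mask] = np.nan
    return STLDecomposition(
        series=MonthlySeries(series.roost_id, series.stratum, series.start, v),
        seasonal=seasonal,
        trend=trend,
        remainder=remainder,
        interpolated=interp_mask,
        span=span,
        n_iter=iterations,
    )


def range_standardize(seasonal: np.ndarray) -> np.ndarray:
    """Rescale a 12-value seasonal component onto [0, 1] by its range."""
    s = np.asarray(seasonal, dtype=float)
    lo, hi = np.min(s), np.max(s)
    if hi == lo:
        raise DegenerateProfileError("seasonal component is constant; range is zero")
    return (s - lo) / (hi - lo)


def seasonal_profile(
    table: CountTable, roost: str, stratum: str, span: float | None = None, n_iter: int = 2
) -> np.ndarray:
    """Range-standardised 12-month seasonal profile for one roost x stratum."""
    series = MonthlySeries.from_table(table, roost, stratum)
    dec = stl_decompose(series, span=span, n_iter=n_iter)
    return range_standardize(dec.seasonal_by_month)
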