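"""Long-term trend regressions of monthly roost-count series.

The time covariate is months elapsed since the first included observation
(0-based), so a per-year change is exactly twelve times the per-month slope.
Pooled series are fitted by simple OLS; stratified family-flock responses
(number of family flocks, mean fledglings per flock) are fitted by ANCOVA
on roost + time after a slope-parallelism check.  p-values are permutation
based when requested, classical otherwise, and the fit labels which.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .counts import CountTable, family_flock_stats
from .exceptions import DesignError
from .permutation import (
    AncovaResult,
    ModelSpec,
    ancova_with_parallelism,
    fit_linear_model,
    permutation_test,
)
from .seasonal import MonthlySeries


@dataclass(frozen=True)
class TrendFit:
    """One linear trend: slope in response units per month."""

    slope: float
    intercept: float
    F: float
    df: tuple[int, int]
    r2: float
    n_obs: int
    p: float
    p_kind: str  # "permutation" | "classical"
    slope_se: float = float("nan")

    @property
    def slope_per_year(self) -> float:
        return 12.0 * self.slope

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Classical t-interval for the per-month slope."""
        half = sps.t.ppf(0.5 + level / 2.0, self.df[1]) * self.slope_se
        return self.slope - half, self.slope + half


def linear_trend(
    series: MonthlySeries | tuple[np.ndarray, np.ndarray],
    permute: bool = False,
    n_perm: int = 4999,
    seed: int = 0,
) -> TrendFit:
    """OLS of a monthly series on months-since-start, optionally permuted.

    Missing months are dropped; the time covariate keeps their calendar
    positions so the slope stays in units per calendar month.
    """
    if isinstance(series, MonthlySeries):
        t = np.arange(len(series), dtype=float)
        y = series.values
    else:
        t, y = (np.asarray(a, dtype=float) for a in series)
    keep = ~np.isnan(y)
    t, y = t[keep], y[keep]
    if len(y) < 3:
        raise ValueError("linear_trend requires at least 3 non-missing observations")
    if np.ptp(t) == 0:
        raise DesignError("time covariate is constant")
    data = pd.DataFrame({"y": y, "time": t})
    spec = ModelSpec.build("y", ["time"], kinds={"time": "covariate"})
    stt = float(np.sum((t - t.mean()) ** 2))
    if permute:
        res = permutation_test(spec, data, n_perm=n_perm, seed=seed, scheme="raw")
        term = res.term("time")
        rss = max(0.0, (1.0 - res.r2) * float(np.sum((y - y.mean()) ** 2)))
        se = float(np.sqrt(rss / term.df[1] / stt))
        return TrendFit(res.coefficients["time"], res.coefficients["(intercept)"],
                        term.F, term.df, res.r2, res.n_obs,
                        term.p_perm, "permutation", slope_se=se)
    fit = fit_linear_model(spec, data)
    term = fit.term("time")
    p = float(sps.f.sf(term.F, *term.df)) if term.F > 0 else 1.0
    se = float(np.sqrt(max(0.0, fit.rss) / term.df[1] / stt))
    return TrendFit(fit.coefficients["time"], fit.coefficients["(intercept)"],
                    term.F, term.df, fit.r2, fit.n_obs, p, "classical", slope_se=se)


@dataclass(frozen=True)
class GroupedTrendFit:
    """Common-slope ANCOVA of a family-flock response across roosts."""

    response: str
    slope: float
    ancova: AncovaResult
    mean_response: float
    sd_response: float
    n_obs: int

    @property
    def slope_per_year(self) -> float:
        return 12.0 * self.slope


def family_flock_table(table: CountTable, roosts: tuple[str, ...] | None) -> pd.DataFrame:
    """Per-record derived family-flock responses with a shared time covariate."""
    df = table.df.copy()
    if roosts is not None:
        df = df[df["roost"].isin([str(r) for r in roosts])]
    df = df.dropna(subset=["family_flock_birds", "fledglings"])
    if df.empty:
        raise ValueError("no records with family-flock counts in the requested roosts")
    derived = [family_flock_stats(m, f)
               for m, f in zip(df["family_flock_birds"], df["fledglings"])]
    df = df.assign(
        n_family_flocks=[n for n, _ in derived],
        mean_fledglings_per_flock=[mu for _, mu in derived],
    )
    origin = (df["year"] * 12 + df["month"]).min()
    df["time"] = (df["year"] * 12 + df["month"] - origin).astype(float)
    return df.reset_index(drop=True)


def grouped_trend(
    table: CountTable,
    response: str,
    roosts: tuple[str, ...] | None = ("1", "2", "3", "4"),
    alpha: float = 0.05,
    n_perm: int = 4999,
    seed: int = 0,
) -> GroupedTrendFit:
    """ANCOVA trend of a derived family-flock response across roosts.

    ``response`` is ``n_family_flocks`` or ``mean_fledglings_per_flock``;
    records where the response is undefined (no family flock seen) are
    dropped.  The default roost subset excludes Roost 5, whose occupancy
    collapsed during monitoring.
    """
    if response not in ("n_family_flocks", "mean_fledglings_per_flock"):
        raise ValueError(f"unknown response {response!r}")
    df = family_flock_table(table, roosts)
    df = df.dropna(subset=[response]).reset_index(drop=True)
    spec = ModelSpec.build(
        response, ["roost", "time", "roost:time"],
        kinds={"roost": "factor", "time": "covariate"},
    )
    anc = ancova_with_parallelism(spec, df, alpha=alpha, n_perm=n_perm, seed=seed)
    slope = anc.final.coefficients["time"]
    y = df[response].to_numpy(dtype=float)
    return GroupedTrendFit(
        response=response,
        slope=float(slope),
        ancova=anc,
        mean_response=float(y.mean()),
        sd_response=float(y.std(ddof=1)),
        n_obs=len(y),
    )
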