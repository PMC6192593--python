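"""Annual stratified summaries and singleton/fledgling demography estimators.

The roosting year is anchored on two windows of the breeding cycle:

* June-July, the pre-reproductive maximum of roost attendance, provides the
  population denominator ("all parrots") for a year;
* August-September, the incubation period, is when one member of each
  incubating pair roosts alone, so the singleton percentage relative to the
  June-July total indexes the minimum proportion of pairs attempting to
  breed that year.

Fledglings counted in family flocks over June-July give an independent,
later-in-life recruitment estimate; the shortfall of the fledgling-based
estimate relative to the singleton-based one is attributed to post-fledging
mortality.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import POOLED_ID, CountTable, SummaryStat, median_iqr, pool_roosts
from .exceptions import DenominatorUnavailableError

DENOMINATOR_MONTHS = (6, 7)   # June-July pre-reproductive maximum
INCUBATION_MONTHS = (8, 9)    # August-September singleton window

SUMMARY_STRATA = ("all_parrots", "singles_pct", "paired_pct", "fledglings_pct")


@dataclass(frozen=True)
class AnnualRoostSummary:
    """Per roost-year summary: Jun-Jul totals and stratified percentages.

    Percentages are relative to ``all_parrots`` (the mean of the available
    June-July totals); ``singles_pct`` uses the August-September singleton
    mean, the others the June-July window.  Unavailable fields are NaN.
    """

    roost_id: str
    year: int
    all_parrots: float
    singles_pct: float
    paired_pct: float
    fledglings_pct: float


@dataclass(frozen=True)
class DemographyEstimates:
    """Breeding-effort and recruitment estimates from pooled summaries."""

    breeding_attempt_proportion: float
    expected_recruits_singleton: int
    expected_recruits_fledgling: int
    post_fledging_loss: float
    fledge_rate: float


def _window_mean(sub: pd.DataFrame, months: tuple[int, ...], column: str) -> float:
    vals = sub.loc[sub["month"].isin(months), column].dropna()
    return float(vals.mean()) if len(vals) else float("nan")


def annual_summary(table: CountTable, roost: str, year: int) -> AnnualRoostSummary:
    """One roost-year's Jun-Jul mean total and stratified percentages."""
    sub = table.df[(table.df["roost"] == str(roost)) & (table.df["year"] == int(year))]
    denom = _window_mean(sub, DENOMINATOR_MONTHS, "all_parrots")
    if math.isnan(denom):
        raise DenominatorUnavailableError(
            f"roost {roost} year {year}: no June-July total counts"
        )
    singles = _window_mean(sub, INCUBATION_MONTHS, "singles")
    pairs = _window_mean(sub, DENOMINATOR_MONTHS, "pairs")
    fledglings = _window_mean(sub, DENOMINATOR_MONTHS, "fledglings")
    to_pct = lambda x: float("nan") if math.isnan(x) or denom == 0 else 100.0 * x / denom
    return AnnualRoostSummary(
        roost_id=str(roost),
        year=int(year),
        all_parrots=denom,
        singles_pct=to_pct(singles),
        paired_pct=to_pct(2.0 * pairs),
        fledglings_pct=to_pct(fledglings),
    )


def summary_table(table: CountTable, include_pooled: bool = True) -> pd.DataFrame:
    """Annual summaries for every roost (and pooled) with median/IQR columns.

    Tidy layout: one row per (roost, stratum), one column per year, plus
    ``median`` and ``iqr`` over the years with defined values.
    """
    tables = {r: table for r in table.roosts()}
    if include_pooled and list(tables) != [POOLED_ID]:
        tables[POOLED_ID] = pool_roosts(table)
    years = sorted(table.df["year"].unique())
    rows = []
    for roost, tab in tables.items():
        per_year: dict[int, AnnualRoostSummary] = {}
        for year in years:
            try:
                per_year[year] = annual_summary(tab, roost, year)
            except DenominatorUnavailableError:
                continue
        for stratum in SUMMARY_STRATA:
            row: dict[str, object] = {"roost": roost, "stratum": stratum}
            vals = []
            for year in years:
                v = getattr(per_year[year], stratum) if year in per_year else float("nan")
                row[str(year)] = v
                if not math.isnan(v):
                    vals.append(v)
            if vals:
                stat = median_iqr(vals)
                row["median"], row["iqr"], row["n"] = stat.median, stat.iqr, stat.n
            else:
                row["median"] = row["iqr"] = float("nan")
                row["n"] = 0
            rows.append(row)
    out = pd.DataFrame(rows)
    order = [r for r in out["roost"].unique() if r != POOLED_ID] + (
        [POOLED_ID] if POOLED_ID in out["roost"].values else []
    )
    out["roost"] = pd.Categorical(out["roost"], categories=order, ordered=True)
    return out.sort_values(["roost", "stratum"], key=lambda s: s if s.name == "roost"
                           else s.map({k: i for i, k in enumerate(SUMMARY_STRATA)})
                           ).reset_index(drop=True)


def breeding_attempt_proportion(summary: AnnualRoostSummary) -> float:
    """Minimum proportion of pairs attempting to breed, from singletons.

    The August-September singleton percentage of the June-July total,
    expressed as a fraction.  NaN propagates when the window was unobserved.
    """
    return summary.singles_pct / 100.0


def expected_recruits(
    pct_median: float, all_parrots_median: float, fledge_rate: float = 1.0
) -> int:
    """Expected annual recruits (birds), rounded half-up to an integer.

    ``pct_median`` is a percentage of the June-July population median;
    ``fledge_rate`` is young fledged per laying female per year.
    """
    if pct_median < 0 or all_parrots_median < 0 or fledge_rate < 0:
        raise ValueError("inputs must be non-negative")
    x = pct_median / 100.0 * all_parrots_median * fledge_rate
    return int(math.floor(x + 0.5))


def post_fledging_loss(singleton_based: float, fledgling_based: float) -> float:
    """Fractional loss between fledging and the mid-year roost maximum.

    1 - fledgling_based / singleton_based, clamped to [0, 1].  A
    fledgling-based estimate exceeding the singleton-based one is clamped to
    zero with a warning; a zero singleton-based estimate yields NaN.
    """
    if singleton_based == 0:
        warnings.warn("singleton-based recruitment is zero; loss undefined", stacklevel=2)
        return float("nan")
    loss = 1.0 - fledgling_based / singleton_based
    if loss < 0:
        warnings.warn(
            "fledgling-based recruitment exceeds singleton-based; loss clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return min(1.0, loss)


def estimate_demography(table: CountTable, fledge_rate: float = 1.0) -> DemographyEstimates:
    """Pooled-roost demography: breeding effort, recruitment, post-fledging loss.

    Uses the pooled summary table's across-year medians: the singleton and
    fledgling percentage medians and the June-July total median.
    """
    summary = summary_table(table, include_pooled=True)
    pooled = summary[summary["roost"] == POOLED_ID].set_index("stratum")
    all_med = float(pooled.loc["all_parrots", "median"])
    singles_med = float(pooled.loc["singles_pct", "median"])
    fledg_med = float(pooled.loc["fledglings_pct", "median"])
    rec_single = expected_recruits(singles_med, all_med, fledge_rate)
    rec_fledg = expected_recruits(fledg_med, all_med, 1.0)
    return DemographyEstimates(
        breeding_attempt_proportion=singles_med / 100.0,
        expected_recruits_singleton=rec_single,
        expected_recruits_fledgling=rec_fledg,
        post_fledging_loss=post_fledging_loss(rec_single, rec_fledg),
        fledge_rate=fledge_rate,
    )
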