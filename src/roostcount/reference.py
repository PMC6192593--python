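"""Published summary tables from the original five-roost monitoring study.

The package ships the values printed by the original southern-Pantanal
Blue-fronted Amazon roost survey (five roosts, July 2004 - July 2009):

* ``monthly_medians()`` - the across-year median count per roost and
  calendar month, including the pooled row;
* ``annual_summaries()`` - the per roost-year June-July totals and
  stratified percentages (singletons of Aug-Sep, paired birds and
  fledglings of Jun-Jul), with the printed across-year median/IQR columns.

These are inputs for reproducing the study's derived quantities (summary
medians, expected recruits, post-fledging loss) without the raw monthly
table, which is deposited externally.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

#: Printed pooled June-July total median used by the recruitment estimate.
#: The printed table rounds the median of the six annual totals
#: (2744, 4207, 4362, 4781, 5475, 5544) to 4571; the unrounded value is 4571.5.
POOLED_ALL_PARROTS_MEDIAN = 4571.5

#: Young fledged per laying female per year, from a twelve-year nest study
#: in the same area (0.9, close to the 0.95 reported for the Argentine Chaco).
FLEDGE_RATE_ESTIMATE = 0.9


def _load(name: str) -> pd.DataFrame:
    with resources.files("roostcount.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, na_values=["-"])


def monthly_medians() -> pd.DataFrame:
    """Across-year median counts, one row per roost (plus pooled), columns 1-12."""
    df = _load("monthly_medians.csv")
    df.columns = ["roost"] + [int(c) for c in df.columns[1:]]
    return df.set_index("roost")


def annual_summaries() -> pd.DataFrame:
    """Annual stratified summaries with the printed median/IQR columns.

    One row per (roost, stratum); year columns are strings '2004'..'2009';
    missing cells (unobserved windows) are NaN.
    """
    return _load("annual_summaries.csv")


def annual_values(roost: str, stratum: str) -> list[float]:
    """The non-missing annual values of one printed summary row."""
    df = annual_summaries()
    row = df[(df["roost"].astype(str) == str(roost)) & (df["stratum"] == stratum)]
    if row.empty:
        raise KeyError(f"no printed row for roost {roost!r}, stratum {stratum!r}")
    years = [c for c in df.columns if c.isdigit()]
    vals = row.iloc[0][years].astype(float)
    return [float(v) for v in vals if pd.notna(v)]
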