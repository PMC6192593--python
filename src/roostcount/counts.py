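"""Flock-size-stratified monthly roost counts: reading, validation, pooling, summaries.

Arriving parrots are classified by flock size: singletons, pairs (dyads of
two paired birds), family flocks (3-6 birds: a parental pair plus 1-4
fledged young), and large flocks (> 6 birds).  ``pairs`` counts dyads, so a
record's total satisfies

    all_parrots = singles + 2*pairs + family_flock_birds + large_flock_birds

``fledglings`` is the number of young in family flocks after discounting the
two parental birds of each flock, so the number of family flocks is the
derived quantity ``(family_flock_birds - fledglings) / 2``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import DuplicationError, FormatError, InvariantError

#: Count strata carried by every record, in canonical column order.
STRATA = (
    "all_parrots",
    "singles",
    "pairs",
    "fledglings",
    "family_flock_birds",
    "large_flock_birds",
)

KEY_COLUMNS = ("roost", "year", "month")
CANONICAL_COLUMNS = KEY_COLUMNS + STRATA

#: Header mapping for the deposited-table dialect.
DEPOSITED_DIALECT = {
    "roost": "roost",
    "year": "year",
    "month": "month",
    "all.parrots": "all_parrots",
    "singles": "singles",
    "pairs": "pairs",
    "fledglings": "fledglings",
    "family.flocks": "family_flock_birds",
    "large.flocks": "large_flock_birds",
}

#: Label used for the across-roost aggregate produced by :func:`pool_roosts`.
POOLED_ID = "pooled"


@dataclass(frozen=True)
class RoostCountRecord:
    """One roost x month observation, stratified by flock size.

    Missing strata are ``None``.  ``month`` is a calendar month 1-12.
    """

    roost_id: str
    year: int
    month: int
    all_parrots: float | None = None
    singles: float | None = None
    pairs: float | None = None
    fledglings: float | None = None
    family_flock_birds: float | None = None
    large_flock_birds: float | None = None


@dataclass(frozen=True)
class SummaryStat:
    """Median / interquartile-range summary of a sample."""

    median: float
    iqr: float
    n: int


@dataclass(frozen=True)
class Violation:
    """One invariant violation located at a record."""

    roost_id: str
    year: int
    month: int
    rule: str
    message: str


@dataclass
class CountTable:
    """An ordered collection of monthly roost-count records.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; missing
    counts are ``NaN``.  At most one record per roost x year x month.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        df = self.df.loc[:, list(CANONICAL_COLUMNS)].copy()
        df["roost"] = df["roost"].astype(str)
        df["year"] = df["year"].astype(int)
        df["month"] = df["month"].astype(int)
        for c in STRATA:
            df[c] = pd.to_numeric(df[c], errors="coerce")
        dup = df.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            keys = df.loc[dup, list(KEY_COLUMNS)].iloc[0].tolist()
            raise DuplicationError(f"duplicate record for roost={keys[0]} {keys[1]}-{keys[2]:02d}")
        if not df["month"].between(1, 12).all():
            raise FormatError("month values must lie in 1..12")
        df = df.sort_values(list(KEY_COLUMNS), kind="stable").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.df.equals(other.df)

    def records(self) -> Iterator[RoostCountRecord]:
        for row in self.df.itertuples(index=False):
            yield RoostCountRecord(
                roost_id=row.roost,
                year=int(row.year),
                month=int(row.month),
                **{s: (None if pd.isna(getattr(row, s)) else float(getattr(row, s))) for s in STRATA},
            )

    def roosts(self) -> list[str]:
        return sorted(self.df["roost"].unique())

    def monitoring_window(self, roost: str) -> tuple[tuple[int, int], tuple[int, int]]:
        """(start, end) year-month of the roost's observed records."""
        sub = self.df[self.df["roost"] == str(roost)]
        if sub.empty:
            raise KeyError(f"unknown roost {roost!r}")
        first, last = sub.iloc[0], sub.iloc[-1]
        return (int(first["year"]), int(first["month"])), (int(last["year"]), int(last["month"]))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def _resolve_dialect(columns: Sequence[str], dialect: str | dict) -> dict[str, str]:
    """Map raw header names onto canonical field names."""
    if isinstance(dialect, dict):
        return {raw: canon for raw, canon in dialect.items() if raw in columns}
    lowered = {c.lower(): c for c in columns}
    mapping: dict[str, str] = {}
    for raw_lower, canon in DEPOSITED_DIALECT.items():
        if raw_lower in lowered:
            mapping[lowered[raw_lower]] = canon
    for canon in CANONICAL_COLUMNS:
        if canon.lower() in lowered:
            mapping[lowered[canon.lower()]] = canon
    return mapping


def read_counts(path: str | Path, dialect: str | dict = "auto") -> CountTable:
    """Read a delimited count table (canonical or deposited-dialect headers).

    Unparseable count cells (including ``-``) become missing values with a
    warning; a missing mandatory column raises :class:`FormatError` naming it.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    mapping = _resolve_dialect(raw.columns, dialect)
    df = raw.rename(columns=mapping)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)} "
            f"(found: {', '.join(raw.columns)})"
        )
    for key in ("year", "month"):
        parsed = pd.to_numeric(df[key], errors="coerce")
        if parsed.isna().any():
            raise FormatError(f"{path}: non-numeric {key!r} value")
        df[key] = parsed.astype(int)
    for c in STRATA:
        cleaned = df[c].replace({"-": None, "": None}).infer_objects(copy=False)
        parsed = pd.to_numeric(cleaned, errors="coerce")
        bad = parsed.isna() & cleaned.notna()
        if bad.any():
            warnings.warn(
                f"{path}: {int(bad.sum())} unparseable cell(s) in column {c!r} treated as missing",
                stacklevel=2,
            )
        df[c] = parsed
    return CountTable(df)


def _record_violations(rec: RoostCountRecord) -> list[Violation]:
    out: list[Violation] = []

    def add(rule: str, message: str) -> None:
        out.append(Violation(rec.roost_id, rec.year, rec.month, rule, message))

    present = {s: getattr(rec, s) for s in STRATA if getattr(rec, s) is not None}
    for name, value in present.items():
        if value < 0:
            add("nonnegative", f"{name} = {value} is negative")
        elif value != int(value):
            add("integral", f"{name} = {value} is not integer-valued")
    if len(present) == len(STRATA):
        total = rec.singles + 2 * rec.pairs + rec.family_flock_birds + rec.large_flock_birds
        if total != rec.all_parrots:
            add(
                "stratification-identity",
                f"all_parrots = {rec.all_parrots} but strata sum to {total}",
            )
    if rec.family_flock_birds is not None and rec.fledglings is not None:
        twice_n = rec.family_flock_birds - rec.fledglings
        if twice_n < 0 or twice_n % 2 != 0:
            add(
                "family-flock-count",
                f"(family_flock_birds - fledglings)/2 = {twice_n / 2} "
                "is not a non-negative integer",
            )
        else:
            n = twice_n / 2
            if n > 0 and not (3 * n <= rec.family_flock_birds <= 6 * n):
                add(
                    "family-flock-size",
                    f"{rec.family_flock_birds} birds in {n:.0f} family flocks "
                    "is outside 3-6 birds per flock",
                )
            if n == 0 and rec.family_flock_birds > 0:
                add(
                    "family-flock-size",
                    f"{rec.family_flock_birds} family-flock birds but zero flocks derived",
                )
    return out


def validate_counts(table: CountTable) -> list[Violation]:
    """Report every stratification-invariant violation; the table is unchanged."""
    out: list[Violation] = []
    for rec in table.records():
        out.extend(_record_violations(rec))
    return out


def family_flock_stats(
    family_flock_birds: float, fledglings: float
) -> tuple[int, float]:
    """Number of family flocks and mean fledglings per flock.

    Each family flock carries two parental birds, so
    ``n = (family_flock_birds - fledglings) / 2``; the mean is ``NaN`` when
    no flock was seen.
    """
    twice_n = family_flock_birds - fledglings
    if twice_n < 0 or twice_n % 2 != 0:
        raise InvariantError(
            f"inconsistent family-flock counts: members={family_flock_birds}, "
            f"fledglings={fledglings}"
        )
    n = int(twice_n // 2)
    if n == 0:
        if family_flock_birds > 0:
            raise InvariantError(
                f"{family_flock_birds} family-flock birds imply zero flocks"
            )
        return 0, float("nan")
    mean = fledglings / n
    if not (1.0 <= mean <= 4.0):
        raise InvariantError(
            f"mean fledglings per flock {mean:.3f} outside the 1-4 young range"
        )
    return n, mean


def pool_roosts(table: CountTable) -> CountTable:
    """Sum counts across roosts month by month.

    A pooled stratum is the sum over the roosts reporting it that month; it
    is missing only when every roost missed it.
    """
    if len(table) == 0:
        raise FormatError("cannot pool an empty table")
    grouped = (
        table.df.groupby(["year", "month"], as_index=False)[list(STRATA)]
        .sum(min_count=1)
    )
    grouped.insert(0, "roost", POOLED_ID)
    return CountTable(grouped)


def median_iqr(values: Iterable[float]) -> SummaryStat:
    """Median and interquartile range with linear-interpolation quartiles.

    Quartiles are the sample quantiles at p = 0.25 and 0.75 with index
    h = (n - 1) p, interpolated linearly between order statistics.
    """
    arr = np.asarray([v for v in values if v is not None and not pd.isna(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr requires at least one non-missing value")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return SummaryStat(median=float(med), iqr=float(q3 - q1), n=int(arr.size))


def monthly_median_table(table: CountTable, stratum: str = "all_parrots") -> pd.DataFrame:
    """Roost x calendar-month grid of across-year medians, plus a pooled row.

    Cell (roost, m) is the median over years of that roost's counts in
    calendar month m; cells with no observation are ``NaN``.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; choose one of {STRATA}")
    frames = {"per-roost": table.df}
    if set(table.df["roost"].unique()) != {POOLED_ID}:
        frames["pooled"] = pool_roosts(table).df
    df = pd.concat(frames.values(), ignore_index=True)
    grid = df.pivot_table(index="roost", columns="month", values=stratum, aggfunc="median")
    grid = grid.reindex(columns=range(1, 13))
    roosts = [r for r in sorted(grid.index) if r != POOLED_ID]
    if POOLED_ID in grid.index:
        roosts.append(POOLED_ID)
    return grid.loc[roosts]
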