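"""Noncumulative return-rate tables by birth cohort.

The noncumulative return rate of a birth cohort in a calendar year is the
percentage of that cohort classified as returned in that year; a child can
flip back to not-returned later, so rates need not be monotone over time.
Tables can be stratified by child type and by mother's or father's education
level. Rates are kept unrounded internally; rounding to one decimal place is
presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .movement import ChildProfile, EDUCATION_LEVELS, StatusPanel

__all__ = [
    "RateCell",
    "BirthBreakdown",
    "SMALL_CELL_THRESHOLD",
    "return_rate",
    "rate_table",
    "breakdown_from_counts",
    "birth_breakdown",
    "format_rate_table",
]

#: Denominators below this are flagged unstable (tiny strata such as the
#: no-schooling education level can swing wildly between years).
SMALL_CELL_THRESHOLD = 30


@dataclass(frozen=True)
class RateCell:
    """One table cell: a percentage with its denominator attached.

    ``rate`` is ``None`` when the denominator is zero (an absent cell, which
    is not the same as a 0% rate).
    """

    rate: float | None
    n: int

    @property
    def small(self) -> bool:
        return 0 < self.n < SMALL_CELL_THRESHOLD


@dataclass(frozen=True)
class BirthBreakdown:
    """Births in one calendar year split by child category.

    ``shares`` are percentages of the year total, rounded to two decimals;
    they are ``None`` (and the row is flagged) for an all-zero year.
    """

    year: int
    type_a: int
    type_b: int
    other: int
    total: int
    shares: dict | None

    @property
    def flagged(self) -> bool:
        return self.shares is None


def return_rate(
    panel: StatusPanel,
    profiles: Sequence[ChildProfile],
    cohort: int,
    year: int,
    stratum: Callable[[ChildProfile], bool] | None = None,
) -> RateCell:
    """Noncumulative return rate of one birth cohort in one year.

    Returns ``100 * returned / cohort size`` over the children of the cohort
    passing the optional ``stratum`` predicate. A year before the cohort's
    birth year is rejected.
    """
    if year < cohort:
        raise ValueError(f"year {year} precedes cohort {cohort}")
    ids = [
        p.child_id
        for p in profiles
        if p.birth_year == cohort and (stratum is None or stratum(p))
    ]
    if not ids:
        return RateCell(rate=None, n=0)
    col = panel.statuses.loc[ids, year]
    returned = int(col.sum())
    return RateCell(rate=100.0 * returned / len(ids), n=len(ids))


def rate_table(
    panel: StatusPanel,
    profiles: Sequence[ChildProfile],
    child_type: str | None = None,
    stratify_by: str = "none",
) -> pd.DataFrame:
    """Full cohort x year (x education level) grid of return rates.

    ``stratify_by`` is ``"none"``, ``"mother_edu"`` or ``"father_edu"``.
    Output is long format with columns ``cohort, year, stratum, rate, n,
    small_cell``; absent cells (empty denominators) are omitted. Small-cell
    denominators are retained and flagged rather than suppressed, since tiny
    strata (e.g. mothers with no schooling) produce unstable rates.
    """
    if stratify_by not in ("none", "mother_edu", "father_edu"):
        raise ValueError(f"unknown stratification {stratify_by!r}")
    pool = [p for p in profiles if child_type is None or p.child_type == child_type]
    cohorts = sorted({p.birth_year for p in pool})
    strata: list[str | None]
    if stratify_by == "none":
        strata = [None]
    else:
        strata = list(EDUCATION_LEVELS)
    records = []
    for cohort in cohorts:
        for year in [y for y in panel.years if y >= cohort]:
            for level in strata:
                if level is None:
                    pred = None
                elif stratify_by == "mother_edu":
                    pred = (lambda lv: lambda p: p.mother_edu == lv)(level)
                else:
                    pred = (lambda lv: lambda p: p.father_edu == lv)(level)
                cell = return_rate(panel, pool, cohort, year, stratum=pred)
                if cell.n == 0:
                    continue
                records.append(
                    {
                        "cohort": cohort,
                        "year": year,
                        "stratum": level if level is not None else "all",
                        "rate": cell.rate,
                        "n": cell.n,
                        "small_cell": cell.small,
                    }
                )
    return pd.DataFrame.from_records(
        records, columns=["cohort", "year", "stratum", "rate", "n", "small_cell"]
    )


def breakdown_from_counts(
    year: int, type_a: int, type_b: int, other: int
) -> BirthBreakdown:
    """Totals and percentage shares recomputed from raw birth counts.

    Shares are rounded to two decimal places. Negative counts are rejected;
    an all-zero year yields undefined shares and a flagged row.
    """
    for name, n in (("type_a", type_a), ("type_b", type_b), ("other", other)):
        if n < 0:
            raise ValueError(f"{name} count for {year} is negative: {n}")
    total = type_a + type_b + other
    if total == 0:
        return BirthBreakdown(year, type_a, type_b, other, total, shares=None)
    shares = {
        "type_a": round(100.0 * type_a / total, 2),
        "type_b": round(100.0 * type_b / total, 2),
        "other": round(100.0 * other / total, 2),
    }
    return BirthBreakdown(year, type_a, type_b, other, total, shares)


def birth_breakdown(
    profiles: Sequence[ChildProfile],
    other_counts: dict[int, int],
) -> list[BirthBreakdown]:
    """Per-year breakdown of births into Type A / Type B / other local births.

    Profiles cover only the study children (Types A and B); counts of other
    births are supplied externally per year. Years are the union of profile
    birth years and ``other_counts`` keys.
    """
    years = sorted({p.birth_year for p in profiles} | set(other_counts))
    out = []
    for year in years:
        a = sum(1 for p in profiles if p.birth_year == year and p.child_type == "A")
        b = sum(1 for p in profiles if p.birth_year == year and p.child_type == "B")
        out.append(breakdown_from_counts(year, a, b, other_counts.get(year, 0)))
    return out


def format_rate_table(table: pd.DataFrame, decimals: int = 1) -> str:
    """Pretty-print a long-format rate table as a cohort x year grid.

    One grid per stratum; rates rounded to ``decimals`` (presentation only),
    small cells marked with an asterisk.
    """
    blocks = []
    for stratum, sub in table.groupby("stratum", sort=True):
        wide = sub.pivot(index="cohort", columns="year", values="rate")
        flags = sub.pivot(index="cohort", columns="year", values="small_cell")
        lines = [f"stratum: {stratum}"]
        header = "cohort  " + "  ".join(f"{y:>6}" for y in wide.columns)
        lines.append(header)
        for cohort in wide.index:
            cells = []
            for y in wide.columns:
                v = wide.at[cohort, y]
                if pd.isna(v):
                    cells.append(" " * 6)
                else:
                    mark = "*" if flags.at[cohort, y] is True else ""
                    cells.append(f"{v:>5.{decimals}f}{mark or ' '}")
            lines.append(f"{cohort:<7} " + " ".join(cells))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks)
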