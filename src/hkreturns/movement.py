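"""Residence classification from border-crossing event logs.

Raw input is a stream of dated arrival/departure events per child, as captured
at the Hong Kong border. This module turns those events into maximal presence
intervals, counts nights of stay per half-year window, and applies the Census
and Statistics Department residence rule — a child counts as "returned" in a
calendar year if they spent at least 31 nights (not necessarily consecutive)
in Hong Kong within either half of that year (the halves split at 30 June).

Conventions
-----------
* A night belongs to the calendar date on which it begins, so an interval
  ``[start, end)`` contributes the nights of ``start`` through ``end - 1 day``.
* A child whose first recorded event is a departure is taken to have been
  living in Hong Kong since the start of their observation period (children
  already resident are classified as returned); symmetrically a trailing
  arrival implies presence through the end of the period. Such intervals are
  flagged ``open_start`` / ``open_end``.
* Same-day arrival+departure pairs are ordered arrival-first, and count zero
  nights.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "MovementEvent",
    "ChildProfile",
    "PresenceInterval",
    "HalfYearWindow",
    "StatusPanel",
    "EDUCATION_LEVELS",
    "CHILD_TYPES",
    "DEFAULT_NIGHT_THRESHOLD",
    "read_events",
    "read_profiles",
    "canonical_order",
    "build_intervals",
    "nights_in_window",
    "nights_in_year",
    "classify_returned",
    "build_status_panel",
]

#: Education codes used on the birth-registration forms: 0 no schooling or
#: kindergarten only, 1 primary, 2 secondary/matriculation, 3 tertiary
#: (non-degree), 4 tertiary (degree), X unknown / not reported.
EDUCATION_LEVELS = ("0", "1", "2", "3", "4", "X")

#: Type A: father is a Hong Kong resident; Type B: neither parent is.
CHILD_TYPES = ("A", "B")

#: Minimum nights in a half-year window for "returned" status.
DEFAULT_NIGHT_THRESHOLD = 31


class Direction(str, Enum):
    """Direction of a border crossing relative to Hong Kong."""

    ARRIVAL = "arrival"
    DEPARTURE = "departure"


@dataclass(frozen=True)
class MovementEvent:
    """One border crossing: a child arrives in or departs from Hong Kong.

    ``source_order`` is the row rank within the input file and breaks ties
    between events of the same child on the same day (after the arrival-first
    rule has been applied).
    """

    child_id: str
    date: date
    direction: Direction
    source_order: int = 0


@dataclass(frozen=True)
class ChildProfile:
    """Registration profile of one study child.

    ``birth_year`` defines the birth cohort (all children born January to
    December of that year). Education codes follow :data:`EDUCATION_LEVELS`.
    """

    child_id: str
    birth_year: int
    child_type: str
    mother_edu: str = "X"
    father_edu: str = "X"

    def __post_init__(self) -> None:
        if self.child_type not in CHILD_TYPES:
            raise ValueError(
                f"child_type must be one of {CHILD_TYPES}, got {self.child_type!r}"
            )
        for name in ("mother_edu", "father_edu"):
            if getattr(self, name) not in EDUCATION_LEVELS:
                raise ValueError(
                    f"{name} must be one of {EDUCATION_LEVELS}, got {getattr(self, name)!r}"
                )


@dataclass(frozen=True)
class PresenceInterval:
    """A maximal stay in Hong Kong, half-open: ``start`` inclusive, ``end`` exclusive.

    ``open_start`` marks presence inferred from a leading departure (the child
    was already in Hong Kong when observation began); ``open_end`` marks a stay
    still running at the end of the observation period.
    """

    child_id: str
    start: date
    end: date
    open_start: bool = False
    open_end: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} after end {self.end}")

    @property
    def nights(self) -> int:
        return (self.end - self.start).days

    def overlap_nights(self, lo: date, hi: date) -> int:
        """Nights of this interval falling on dates in ``[lo, hi)``."""
        a = max(self.start, lo)
        b = min(self.end, hi)
        return max(0, (b - a).days)


@dataclass(frozen=True)
class HalfYearWindow:
    """One half of a calendar year: H1 = 1 Jan–30 Jun, H2 = 1 Jul–31 Dec."""

    year: int
    half: int  # 1 or 2

    def __post_init__(self) -> None:
        if self.half not in (1, 2):
            raise ValueError(f"half must be 1 or 2, got {self.half}")

    @property
    def start(self) -> date:
        return date(self.year, 1 if self.half == 1 else 7, 1)

    @property
    def end(self) -> date:
        """Exclusive end: 1 Jul for H1, 1 Jan of the next year for H2."""
        return date(self.year, 7, 1) if self.half == 1 else date(self.year + 1, 1, 1)

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days


# ---------------------------------------------------------------------------
# Reading


def _parse_date(text: str) -> date:
    return date.fromisoformat(text.strip())


def read_events(path: str | Path) -> list[MovementEvent]:
    """Read movement events from a CSV with header ``child_id,date,direction``.

    Events are returned grouped by child and, within a child, ordered by
    ``(date, source_order)``. Malformed dates or unknown directions raise
    ``ValueError`` naming the offending row (1-based, counting the header as
    row 1). Exact duplicate rows are kept but logged.
    """
    path = Path(path)
    events: list[MovementEvent] = []
    seen: set[tuple[str, str, str]] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"child_id", "date", "direction"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: header must contain columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            raw = (row["child_id"], row["date"], row["direction"])
            try:
                when = _parse_date(row["date"])
            except ValueError as exc:
                raise ValueError(f"{path}: row {i}: bad date {row['date']!r}") from exc
            try:
                direction = Direction(row["direction"].strip().lower())
            except ValueError:
                raise ValueError(
                    f"{path}: row {i}: unknown direction {row['direction']!r} "
                    f"(expected 'arrival' or 'departure')"
                ) from None
            if raw in seen:
                logger.info("%s: row %d duplicates an earlier row (kept)", path, i)
            seen.add(raw)
            events.append(MovementEvent(row["child_id"], when, direction, source_order=i))
    events.sort(key=lambda e: (e.child_id, e.date, e.source_order))
    return events


def read_profiles(path: str | Path) -> list[ChildProfile]:
    """Read child profiles from a CSV with header
    ``child_id,birth_year,child_type,mother_edu,father_edu``.

    Missing/blank education fields map to the unknown category ``"X"``.
    """
    path = Path(path)
    profiles: list[ChildProfile] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"child_id", "birth_year", "child_type"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: header must contain columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                birth_year = int(row["birth_year"])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: row {i}: bad birth_year {row['birth_year']!r}"
                ) from exc
            try:
                profiles.append(
                    ChildProfile(
                        child_id=row["child_id"],
                        birth_year=birth_year,
                        child_type=row["child_type"].strip(),
                        mother_edu=(row.get("mother_edu") or "X").strip() or "X",
                        father_edu=(row.get("father_edu") or "X").strip() or "X",
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from None
    return profiles


# ---------------------------------------------------------------------------
# Interval construction


def canonical_order(events_of_one_day: Sequence[MovementEvent]) -> list[MovementEvent]:
    """Order the events of one child on one day: arrivals before departures.

    When a child has both an arrival and a departure on the same day the
    arrival is assumed to have happened first. The sort is stable, so the
    original file order is preserved within each direction.
    """
    if events_of_one_day:
        first = events_of_one_day[0]
        for e in events_of_one_day[1:]:
            if e.child_id != first.child_id or e.date != first.date:
                raise ValueError("canonical_order expects events of one child on one day")
    return sorted(events_of_one_day, key=lambda e: e.direction is Direction.DEPARTURE)


def canonicalize(events: Sequence[MovementEvent]) -> list[MovementEvent]:
    """Apply the same-day arrival-first rule across a full event stream."""
    ordered = sorted(events, key=lambda e: (e.child_id, e.date, e.source_order))
    out: list[MovementEvent] = []
    i = 0
    while i < len(ordered):
        j = i
        while (
            j < len(ordered)
            and ordered[j].child_id == ordered[i].child_id
            and ordered[j].date == ordered[i].date
        ):
            j += 1
        out.extend(canonical_order(ordered[i:j]))
        i = j
    return out


def build_intervals(
    events: Sequence[MovementEvent],
    period_start: date,
    period_end: date,
) -> list[PresenceInterval]:
    """Convert one child's canonically ordered events into presence intervals.

    An arrival opens a stay and the next departure closes it (exclusive end at
    the departure date, so a same-day round trip counts zero nights). A child
    whose record begins with a departure is taken to have been present since
    ``period_start`` (``open_start=True``); a record ending with an arrival
    yields presence through ``period_end`` exclusive (``open_end=True``).
    Consecutive arrivals (or departures) without the opposite event in between
    are collapsed onto the first one, with a data-quality log message.

    ``period_end`` is exclusive: pass 1 Jan of the year after the observation
    window.
    """
    if period_start > period_end:
        raise ValueError("period_start must not be after period_end")
    if not events:
        return []
    child = events[0].child_id
    prev: MovementEvent | None = None
    for e in events:
        if e.child_id != child:
            raise ValueError("build_intervals expects events of a single child")
        # Only dates are checked: the arrival-first rule may legitimately
        # invert the file order of a same-day pair.
        if prev is not None and e.date < prev.date:
            raise ValueError(
                f"events out of order for child {child}: {prev.date} then {e.date}"
            )
        prev = e

    intervals: list[PresenceInterval] = []
    inside = False
    open_start = False
    current_start = period_start
    for e in events:
        if e.direction is Direction.ARRIVAL:
            if inside:
                logger.warning(
                    "child %s: arrival on %s while already present; collapsed",
                    child,
                    e.date,
                )
                continue
            inside = True
            open_start = False
            current_start = e.date
        else:  # departure
            if not inside:
                if intervals:
                    logger.warning(
                        "child %s: departure on %s while already absent; collapsed",
                        child,
                        e.date,
                    )
                    continue
                # Leading departure: present since the start of observation.
                inside = True
                open_start = True
                current_start = period_start
            intervals.append(
                PresenceInterval(
                    child_id=child,
                    start=current_start,
                    end=max(e.date, current_start),
                    open_start=open_start,
                )
            )
            inside = False
    if inside:
        intervals.append(
            PresenceInterval(
                child_id=child,
                start=current_start,
                end=max(period_end, current_start),
                open_start=open_start,
                open_end=True,
            )
        )
    # Same-day round trips (start == end) cover no night; drop them so the
    # strict start < end invariant holds for every surviving interval.
    return [iv for iv in intervals if iv.nights > 0]


# ---------------------------------------------------------------------------
# Night counting and classification


def nights_in_window(
    intervals: Iterable[PresenceInterval], window: HalfYearWindow
) -> int:
    """Number of nights within the half-year window covered by the intervals.

    Intervals are assumed pairwise disjoint, so overlaps simply add. The
    result is bounded by the number of days in the window.
    """
    total = sum(iv.overlap_nights(window.start, window.end) for iv in intervals)
    return min(total, window.n_days)


def nights_in_year(intervals: Iterable[PresenceInterval], year: int) -> int:
    """Nights attributed to a calendar year (sum over its two halves)."""
    ivs = list(intervals)
    return nights_in_window(ivs, HalfYearWindow(year, 1)) + nights_in_window(
        ivs, HalfYearWindow(year, 2)
    )


def classify_returned(
    intervals: Iterable[PresenceInterval],
    year: int,
    night_threshold: int = DEFAULT_NIGHT_THRESHOLD,
) -> int:
    """Returned status of a child in ``year``: 1 if at least ``night_threshold``
    nights were spent in Hong Kong within either half of the year, else 0.

    The nights need not be consecutive — only the per-window total matters.
    """
    ivs = list(intervals)
    if nights_in_window(ivs, HalfYearWindow(year, 1)) >= night_threshold:
        return 1
    if nights_in_window(ivs, HalfYearWindow(year, 2)) >= night_threshold:
        return 1
    return 0


# ---------------------------------------------------------------------------
# Status panel


@dataclass
class StatusPanel:
    """Per-child, per-year binary returned status.

    ``statuses`` is a wide DataFrame: index ``child_id``, one integer column
    per calendar year, values 0/1 (pandas NA for years before a child's birth
    year). Each child is covered from their birth year through
    ``observation_end_year``.
    """

    statuses: pd.DataFrame
    observation_end_year: int

    def status(self, child_id: str, year: int) -> int:
        value = self.statuses.at[child_id, year]
        if pd.isna(value):
            raise KeyError(f"child {child_id} not observed in {year}")
        return int(value)

    @property
    def years(self) -> list[int]:
        return [int(c) for c in self.statuses.columns]

    @property
    def n_children(self) -> int:
        return len(self.statuses)

    def cohort_matrix(self, child_ids: Sequence[str], cohort: int):
        """Dense 0/1 matrix (children x years) for one birth cohort,
        spanning ``cohort`` .. ``observation_end_year``."""
        years = [y for y in self.years if cohort <= y <= self.observation_end_year]
        sub = self.statuses.loc[list(child_ids), years]
        return sub.to_numpy(dtype=float).astype(int), years

    def to_csv(self, path: str | Path) -> None:
        out = self.statuses.copy()
        out.columns = [str(c) for c in out.columns]
        out.to_csv(path, index_label="child_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "StatusPanel":
        df = pd.read_csv(path, index_col="child_id", dtype={"child_id": str})
        df.columns = [int(c) for c in df.columns]
        df = df.astype("Int64")
        return cls(statuses=df, observation_end_year=max(df.columns))


def build_status_panel(
    profiles: Sequence[ChildProfile],
    events: Sequence[MovementEvent],
    observation_end_year: int,
    observation_start_year: int | None = None,
    night_threshold: int = DEFAULT_NIGHT_THRESHOLD,
) -> StatusPanel:
    """Classify every child for every year from their birth year to
    ``observation_end_year``.

    Children with no movement events are not-returned (0) throughout. Events
    whose ``child_id`` has no profile raise ``ValueError`` listing the orphan
    ids. Each child's observation period starts at the later of
    ``observation_start_year`` (default: the earliest birth year) and their
    birth year, implementing the rule that already-resident children — whose
    first event may be a departure — count as returned from the start.
    """
    known = {p.child_id for p in profiles}
    orphans = sorted({e.child_id for e in events} - known)
    if orphans:
        raise ValueError(f"events reference unknown child ids: {orphans}")

    if observation_start_year is None:
        observation_start_year = min((p.birth_year for p in profiles), default=observation_end_year)

    by_child: dict[str, list[MovementEvent]] = {}
    for e in canonicalize(events):
        by_child.setdefault(e.child_id, []).append(e)

    all_years = list(
        range(min((p.birth_year for p in profiles), default=observation_end_year),
              observation_end_year + 1)
    )
    period_end = date(observation_end_year + 1, 1, 1)
    rows: dict[str, list] = {}
    for p in profiles:
        start_year = max(observation_start_year, p.birth_year)
        period_start = date(start_year, 1, 1)
        intervals = build_intervals(by_child.get(p.child_id, []), period_start, period_end)
        row: list = []
        for y in all_years:
            if y < p.birth_year:
                row.append(pd.NA)
            else:
                row.append(classify_returned(intervals, y, night_threshold))
        rows[p.child_id] = row

    df = pd.DataFrame.from_dict(rows, orient="index", columns=all_years).astype("Int64")
    df.index.name = "child_id"
    return StatusPanel(statuses=df, observation_end_year=observation_end_year)
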