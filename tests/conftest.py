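"""Shared fixtures: tiny hand-checkable populations and event streams."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from hkreturns import (
    ChildProfile,
    Direction,
    HalfYearWindow,
    MovementEvent,
    PresenceInterval,
    SimConfig,
)


@pytest.fixture
def small_profiles() -> list[ChildProfile]:
    return [
        ChildProfile("a1", 2010, "A", "2", "3"),
        ChildProfile("a2", 2010, "A", "1", "2"),
        ChildProfile("b1", 2010, "B", "4", "4"),
        ChildProfile("b2", 2011, "B", "X", "2"),
    ]


@pytest.fixture
def sim_config() -> SimConfig:
    return SimConfig(
        cohort_sizes={2005: 120, 2008: 120},
        observation_end_year=2016,
        seed=20240601,
    )


def ev(child: str, iso: str, direction: str, order: int = 0) -> MovementEvent:
    return MovementEvent(child, date.fromisoformat(iso), Direction(direction), order)


def brute_force_nights(intervals: list[PresenceInterval], window: HalfYearWindow) -> int:
    """Independent oracle: walk every date of the window and test membership."""
    count = 0
    d = window.start
    while d < window.end:
        if any(iv.start <= d < iv.end for iv in intervals):
            count += 1
        d += timedelta(days=1)
    return count
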