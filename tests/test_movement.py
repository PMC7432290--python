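"""Residence classification from event logs: intervals, nights, statuses."""

from __future__ import annotations

from datetime import date, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from hkreturns import (
    Direction,
    HalfYearWindow,
    MovementEvent,
    PresenceInterval,
    build_intervals,
    build_status_panel,
    canonical_order,
    classify_returned,
    nights_in_window,
    read_events,
)
from hkreturns.movement import canonicalize, nights_in_year

from conftest import brute_force_nights, ev


# ---------------------------------------------------------------------------
# Reading

class TestReadEvents:
    def test_reads_and_groups_by_child(self, tmp_path):
        p = tmp_path / "events.csv"
        p.write_text(
            "child_id,date,direction\n"
            "c2,2010-05-01,arrival\n"
            "c1,2010-03-01,arrival\n"
            "c1,2010-04-01,departure\n"
        )
        events = read_events(p)
        assert len(events) == 3
        assert [e.child_id for e in events] == ["c1", "c1", "c2"]
        assert events[0].direction is Direction.ARRIVAL

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "events.csv"
        p.write_text("child_id,date,direction\n")
        assert read_events(p) == []

    @pytest.mark.parametrize(
        "bad_row, fragment",
        [
            ("c1,2010-01-01,exit", "row 2"),
            ("c1,01/02/2010,arrival", "row 2"),
        ],
    )
    def test_malformed_rows_name_their_row(self, tmp_path, bad_row, fragment):
        p = tmp_path / "events.csv"
        p.write_text(f"child_id,date,direction\n{bad_row}\n")
        with pytest.raises(ValueError, match=fragment):
            read_events(p)


# ---------------------------------------------------------------------------
# Same-day ordering

class TestCanonicalOrder:
    def test_arrival_precedes_departure(self):
        day = [ev("c", "2010-01-05", "departure", 1), ev("c", "2010-01-05", "arrival", 2)]
        ordered = canonical_order(day)
        assert [e.direction for e in ordered] == [Direction.ARRIVAL, Direction.DEPARTURE]

    def test_singleton_unchanged(self):
        day = [ev("c", "2010-01-05", "arrival", 1)]
        assert canonical_order(day) == day

    def test_mixed_same_day_is_stable_sort_on_direction(self):
        # Independent oracle: a stable sort with departures-last key.
        day = [
            ev("c", "2010-01-05", "arrival", 1),
            ev("c", "2010-01-05", "arrival", 2),
            ev("c", "2010-01-05", "departure", 3),
        ]
        expected = sorted(day, key=lambda e: e.direction is Direction.DEPARTURE)
        assert canonical_order(day) == expected
        assert [e.source_order for e in canonical_order(day)] == [1, 2, 3]

    def test_rejects_events_of_different_days(self):
        with pytest.raises(ValueError):
            canonical_order([ev("c", "2010-01-05", "arrival"),
                             ev("c", "2010-01-06", "arrival")])


# ---------------------------------------------------------------------------
# Interval construction

class TestBuildIntervals:
    START = date(2010, 1, 1)
    END = date(2012, 1, 1)

    def test_arrival_departure_pair(self):
        ivs = build_intervals(
            [ev("c", "2010-02-01", "arrival", 1), ev("c", "2010-03-01", "departure", 2)],
            self.START, self.END,
        )
        assert len(ivs) == 1
        assert (ivs[0].start, ivs[0].end) == (date(2010, 2, 1), date(2010, 3, 1))
        assert not ivs[0].open_start and not ivs[0].open_end

    def test_leading_departure_means_resident_since_period_start(self):
        ivs = build_intervals([ev("c", "2010-06-01", "departure", 1)],
                              self.START, self.END)
        assert len(ivs) == 1
        assert ivs[0].start == self.START
        assert ivs[0].open_start

    def test_trailing_arrival_runs_to_period_end(self):
        # Day-count oracle: 2010-12-01 through 2011-12-31 is 396 nights.
        ivs = build_intervals([ev("c", "2010-12-01", "arrival", 1)],
                              self.START, self.END)
        assert len(ivs) == 1
        assert ivs[0].end == self.END and ivs[0].open_end
        assert ivs[0].nights == 396

    def test_no_events_no_intervals(self):
        assert build_intervals([], self.START, self.END) == []

    def test_same_day_round_trip_counts_zero_nights(self):
        ivs = build_intervals(
            [ev("c", "2010-02-01", "arrival", 1), ev("c", "2010-02-01", "departure", 2)],
            self.START, self.END,
        )
        assert ivs == []

    def test_duplicate_arrivals_collapse_to_first(self, caplog):
        with caplog.at_level("WARNING"):
            ivs = build_intervals(
                [
                    ev("c", "2010-02-01", "arrival", 1),
                    ev("c", "2010-02-10", "arrival", 2),
                    ev("c", "2010-03-01", "departure", 3),
                ],
                self.START, self.END,
            )
        assert len(ivs) == 1
        assert ivs[0].start == date(2010, 2, 1)
        assert "collapsed" in caplog.text

    def test_out_of_order_events_rejected(self):
        with pytest.raises(ValueError, match="out of order"):
            build_intervals(
                [ev("c", "2010-03-01", "departure", 2), ev("c", "2010-02-01", "arrival", 1)],
                self.START, self.END,
            )

    def test_intervals_disjoint_and_sorted(self):
        events = [
            ev("c", "2010-02-01", "arrival", 1), ev("c", "2010-03-01", "departure", 2),
            ev("c", "2010-05-01", "arrival", 3), ev("c", "2010-06-01", "departure", 4),
        ]
        ivs = build_intervals(events, self.START, self.END)
        assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))


# ---------------------------------------------------------------------------
# Night counting

class TestNights:
    def test_partial_interval_h1(self):
        iv = PresenceInterval("c", date(2010, 1, 1), date(2010, 2, 15))
        assert nights_in_window([iv], HalfYearWindow(2010, 1)) == 45

    def test_no_intervals(self):
        assert nights_in_window([], HalfYearWindow(2010, 1)) == 0

    def test_full_year_h1_is_calendar_day_count(self):
        iv = PresenceInterval("c", date(2010, 1, 1), date(2011, 1, 1))
        assert nights_in_window([iv], HalfYearWindow(2010, 1)) == 181
        assert nights_in_window([iv], HalfYearWindow(2010, 2)) == 184

    def test_leap_year_h1(self):
        iv = PresenceInterval("c", date(2012, 1, 1), date(2013, 1, 1))
        assert nights_in_window([iv], HalfYearWindow(2012, 1)) == 182


# ---------------------------------------------------------------------------
# Classification rule

class TestClassifyReturned:
    def test_31_scattered_nights_in_one_half_is_returned(self):
        # Spread over four separate visits, none consecutive with the next.
        ivs = [
            PresenceInterval("c", date(2010, 1, 10), date(2010, 1, 20)),  # 10
            PresenceInterval("c", date(2010, 2, 10), date(2010, 2, 20)),  # 10
            PresenceInterval("c", date(2010, 3, 10), date(2010, 3, 20)),  # 10
            PresenceInterval("c", date(2010, 4, 10), date(2010, 4, 11)),  # 1
        ]
        assert sum(iv.nights for iv in ivs) == 31
        assert classify_returned(ivs, 2010) == 1

    def test_30_plus_30_split_across_halves_is_not_returned(self):
        ivs = [
            PresenceInterval("c", date(2010, 6, 1), date(2010, 7, 1)),  # 30 in H1
            PresenceInterval("c", date(2010, 8, 1), date(2010, 8, 31)),  # 30 in H2
        ]
        assert nights_in_window(ivs, HalfYearWindow(2010, 1)) == 30
        assert nights_in_window(ivs, HalfYearWindow(2010, 2)) == 30
        assert classify_returned(ivs, 2010) == 0

    def test_continuous_residence_all_year(self):
        ivs = [PresenceInterval("c", date(2010, 1, 1), date(2011, 1, 1))]
        assert classify_returned(ivs, 2010) == 1

    def test_custom_threshold(self):
        ivs = [PresenceInterval("c", date(2010, 3, 1), date(2010, 3, 21))]
        assert classify_returned(ivs, 2010, night_threshold=20) == 1
        assert classify_returned(ivs, 2010, night_threshold=21) == 0


# ---------------------------------------------------------------------------
# Status panel

class TestStatusPanel:
    def test_child_without_events_is_never_returned(self, small_profiles):
        panel = build_status_panel(small_profiles, [], observation_end_year=2012)
        for year in (2010, 2011, 2012):
            assert panel.status("a1", year) == 0

    def test_resident_from_birth_is_returned_throughout(self, small_profiles):
        # Only event is a departure after years of residence: the child was
        # already living in Hong Kong, so every year up to it counts.
        events = [ev("a1", "2012-12-01", "departure", 1)]
        panel = build_status_panel(small_profiles, events, observation_end_year=2012)
        assert [panel.status("a1", y) for y in (2010, 2011, 2012)] == [1, 1, 1]

    def test_years_before_birth_are_missing(self, small_profiles):
        panel = build_status_panel(small_profiles, [], observation_end_year=2012)
        with pytest.raises(KeyError):
            panel.status("b2", 2010)  # born 2011

    def test_orphan_event_ids_rejected(self, small_profiles):
        events = [ev("ghost", "2011-02-01", "arrival", 1)]
        with pytest.raises(ValueError, match="ghost"):
            build_status_panel(small_profiles, events, observation_end_year=2012)

    def test_csv_round_trip(self, small_profiles, tmp_path):
        events = [ev("a1", "2011-02-01", "arrival", 1),
                  ev("a1", "2011-04-01", "departure", 2)]
        panel = build_status_panel(small_profiles, events, observation_end_year=2012)
        panel.to_csv(tmp_path / "panel.csv")
        back = type(panel).from_csv(tmp_path / "panel.csv")
        assert back.statuses.equals(panel.statuses)

    def test_panel_matches_per_child_oracle(self, sim_config):
        # Independent recomputation: classify each child by hand from their
        # own intervals and compare cell for cell.
        from hkreturns import generate_profiles, generate_status_paths, render_events
        from hkreturns.movement import build_intervals as bi

        import dataclasses
        cfg = dataclasses.replace(sim_config, cohort_sizes={2008: 100})
        profiles = generate_profiles(cfg)
        truth = generate_status_paths(cfg, profiles)
        events = render_events(truth, cfg)
        panel = build_status_panel(profiles, events, cfg.observation_end_year)

        by_child: dict[str, list[MovementEvent]] = {}
        for e in canonicalize(events):
            by_child.setdefault(e.child_id, []).append(e)
        for p in profiles:
            ivs = bi(by_child.get(p.child_id, []), date(p.birth_year, 1, 1),
                     date(cfg.observation_end_year + 1, 1, 1))
            for year in range(p.birth_year, cfg.observation_end_year + 1):
                assert panel.status(p.child_id, year) == classify_returned(ivs, year)


# ---------------------------------------------------------------------------
# Properties

def _random_child_events(draw_days: list[int], directions: list[bool]) -> list[MovementEvent]:
    base = date(2010, 1, 1)
    events = [
        MovementEvent("c", base + timedelta(days=d),
                      Direction.ARRIVAL if a else Direction.DEPARTURE, i)
        for i, (d, a) in enumerate(zip(draw_days, directions))
    ]
    return canonicalize(events)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    days=st.lists(st.integers(min_value=0, max_value=1095), min_size=0, max_size=20),
    flips=st.lists(st.booleans(), min_size=20, max_size=20),
)
def test_nights_match_brute_force_oracle(days, flips):
    """For arbitrary event streams, interval night counts equal a
    date-by-date membership count."""
    events = _random_child_events(sorted(days), flips[: len(days)])
    ivs = build_intervals(events, date(2010, 1, 1), date(2013, 1, 1))
    for year in (2010, 2011, 2012):
        for half in (1, 2):
            w = HalfYearWindow(year, half)
            assert nights_in_window(ivs, w) == brute_force_nights(ivs, w)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    days=st.lists(st.integers(min_value=0, max_value=1095), min_size=0, max_size=20),
    flips=st.lists(st.booleans(), min_size=20, max_size=20),
)
def test_night_conservation_across_halves(days, flips):
    """H1 + H2 nights equal the nights attributed to the whole year."""
    events = _random_child_events(sorted(days), flips[: len(days)])
    ivs = build_intervals(events, date(2010, 1, 1), date(2013, 1, 1))
    for year in (2010, 2011, 2012):
        whole = sum(iv.overlap_nights(date(year, 1, 1), date(year + 1, 1, 1))
                    for iv in ivs)
        assert nights_in_year(ivs, year) == whole


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    starts=st.lists(st.integers(min_value=0, max_value=700), min_size=1, max_size=8,
                    unique=True),
    lengths=st.lists(st.integers(min_value=1, max_value=40), min_size=8, max_size=8),
)
def test_adding_an_interval_never_decreases_nights_or_flips_status_off(starts, lengths):
    base = date(2010, 1, 1)
    raw = sorted(zip(sorted(starts), lengths))
    ivs: list[PresenceInterval] = []
    cursor = -1
    for s, ln in raw:  # keep intervals disjoint
        s = max(s, cursor + 1)
        ivs.append(PresenceInterval("c", base + timedelta(days=s),
                                    base + timedelta(days=s + ln)))
        cursor = s + ln
    smaller = ivs[:-1]
    for year in (2010, 2011):
        for half in (1, 2):
            w = HalfYearWindow(year, half)
            assert nights_in_window(ivs, w) >= nights_in_window(smaller, w)
        assert classify_returned(ivs, year) >= classify_returned(smaller, year)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    days=st.lists(st.integers(min_value=0, max_value=1095), min_size=0, max_size=20),
    flips=st.lists(st.booleans(), min_size=20, max_size=20),
)
def test_canonicalize_is_idempotent(days, flips):
    events = _random_child_events(sorted(days), flips[: len(days)])
    assert canonicalize(events) == events
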