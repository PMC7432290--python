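"""Synthetic study populations: profiles, Markov status paths, event streams.

The real movement records (hundreds of thousands of children observed at the
Hong Kong border over more than a decade) are confidential, so this module
generates populations with the statistical structure the analysis assumes:

* child profiles stratified by birth cohort, child type (A: father a Hong
  Kong resident; B: not) and parental education;
* yearly returned-status paths following the two-state Markov chain with
  cohort- and type-specific (theta1, theta2) and a Bernoulli birth state;
* arrival/departure event streams that *render* those status paths — stays
  of at least 31 nights inside one half-year window for returned years,
  nothing or short visits (at most 30 nights per window) otherwise.

The central contract is the round trip: classifying the rendered events with
:mod:`hkreturns.movement` reproduces the generating status panel cell for
cell. Renderings deliberately exercise the awkward cases of real logs —
children already resident when observation starts (leading departures),
stays running past the observation end (trailing arrivals), residence spells
spanning New Year, and optionally scattered non-consecutive nights.

Everything is deterministic for a fixed seed; independent substreams are
used for profiles, paths and events so each stage is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .movement import (
    ChildProfile,
    Direction,
    EDUCATION_LEVELS,
    MovementEvent,
    StatusPanel,
)

__all__ = ["SimConfig", "generate_profiles", "generate_status_paths",
           "render_events", "simulate_status_matrix"]

# Parental education profiles: type B parents are on average better educated
# than type A parents, with small no-schooling and unknown shares.
_DEFAULT_EDU = {
    "A": {"0": 0.02, "1": 0.15, "2": 0.55, "3": 0.12, "4": 0.10, "X": 0.06},
    "B": {"0": 0.01, "1": 0.08, "2": 0.45, "3": 0.18, "4": 0.22, "X": 0.06},
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic study population.

    Defaults sketch the real cohort structure: type A children are the
    smaller group with high return propensity (they mostly have a parent in
    Hong Kong), type B children return rarely and slowly. ``theta_a`` /
    ``theta_b`` are (theta1, theta2) pairs applied to every cohort of that
    type unless overridden per (type, cohort) in ``theta_by_cohort``; the
    birth-state probabilities ``p0_a`` / ``p0_b`` work the same way with
    ``p0_by_cohort``.

    Rendering knobs: ``persist_prob`` is the chance that two consecutive
    returned years are rendered as one residence spell crossing New Year;
    ``born_resident_prob`` the chance a child returned in their birth year is
    rendered as already resident (first event a departure); ``visit_prob``
    the chance a not-returned year still shows a short (< 31-night) visit;
    ``scattered_prob`` the chance a returned year is rendered as several
    non-consecutive short stays instead of one block.
    """

    cohort_sizes: Mapping[int, int]
    observation_end_year: int
    seed: int = 0
    type_a_share: float = 0.25
    mother_edu_dist: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {t: dict(d) for t, d in _DEFAULT_EDU.items()}
    )
    father_edu_dist: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {t: dict(d) for t, d in _DEFAULT_EDU.items()}
    )
    theta_a: tuple[float, float] = (0.50, 0.90)
    theta_b: tuple[float, float] = (0.92, 0.85)
    theta_by_cohort: Mapping[tuple[str, int], tuple[float, float]] = field(
        default_factory=dict
    )
    p0_a: float = 0.60
    p0_b: float = 0.10
    p0_by_cohort: Mapping[tuple[str, int], float] = field(default_factory=dict)
    persist_prob: float = 0.5
    born_resident_prob: float = 0.5
    visit_prob: float = 0.3
    scattered_prob: float = 0.0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.cohort_sizes.values()):
            raise ValueError("cohort sizes must be nonnegative")
        if self.cohort_sizes and max(self.cohort_sizes) > self.observation_end_year:
            raise ValueError("cohorts must be born by the observation end year")
        probs = [self.type_a_share, self.p0_a, self.p0_b, self.persist_prob,
                 self.born_resident_prob, self.visit_prob, self.scattered_prob]
        probs += [t for pair in (self.theta_a, self.theta_b) for t in pair]
        probs += [t for pair in self.theta_by_cohort.values() for t in pair]
        probs += list(self.p0_by_cohort.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for dist in (self.mother_edu_dist, self.father_edu_dist):
            for t, weights in dist.items():
                if set(weights) != set(EDUCATION_LEVELS):
                    raise ValueError(f"education weights for type {t} must cover "
                                     f"{EDUCATION_LEVELS}")
                if abs(sum(weights.values()) - 1.0) > 1e-9:
                    raise ValueError(f"education weights for type {t} must sum to 1")

    def theta(self, child_type: str, cohort: int) -> tuple[float, float]:
        if (child_type, cohort) in self.theta_by_cohort:
            return self.theta_by_cohort[(child_type, cohort)]
        return self.theta_a if child_type == "A" else self.theta_b

    def p0(self, child_type: str, cohort: int) -> float:
        if (child_type, cohort) in self.p0_by_cohort:
            return self.p0_by_cohort[(child_type, cohort)]
        return self.p0_a if child_type == "A" else self.p0_b


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # Independent substreams per stage keyed on (seed, stream id).
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_profiles(config: SimConfig) -> list[ChildProfile]:
    """Draw child profiles cohort by cohort.

    Child ids encode the cohort for readability (``C2006-000123``). Types are
    i.i.d. Bernoulli(``type_a_share``); mother's and father's education are
    drawn independently from the type-specific categorical distributions.
    """
    rng = _rng(config, 0)
    profiles: list[ChildProfile] = []
    for cohort in sorted(config.cohort_sizes):
        size = config.cohort_sizes[cohort]
        if size == 0:
            continue
        types = np.where(rng.random(size) < config.type_a_share, "A", "B")
        for i in range(size):
            t = str(types[i])
            levels = list(EDUCATION_LEVELS)
            m = rng.choice(levels, p=[config.mother_edu_dist[t][k] for k in levels])
            f = rng.choice(levels, p=[config.father_edu_dist[t][k] for k in levels])
            profiles.append(
                ChildProfile(
                    child_id=f"C{cohort}-{i:06d}",
                    birth_year=cohort,
                    child_type=t,
                    mother_edu=str(m),
                    father_edu=str(f),
                )
            )
    return profiles


def simulate_status_matrix(
    n: int,
    n_years: int,
    theta1: float,
    theta2: float,
    p0: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``n`` independent status paths of length ``n_years``.

    The birth state is Bernoulli(p0); each subsequent year follows the
    two-state chain. Returns an (n, n_years) 0/1 array. This is the fast path
    used for estimator-recovery studies.
    """
    out = np.empty((n, n_years), dtype=np.int8)
    out[:, 0] = rng.random(n) < p0
    for t in range(1, n_years):
        u = rng.random(n)
        out[:, t] = np.where(out[:, t - 1] == 1, u < theta2, u < 1.0 - theta1)
    return out


def generate_status_paths(
    config: SimConfig, profiles: Sequence[ChildProfile] | None = None
) -> StatusPanel:
    """Run the generating chain for every child, birth year to observation end.

    If ``profiles`` is omitted they are regenerated from the config seed, so
    the call is reproducible either way. Children are grouped by (type,
    cohort) and simulated vectorised with the group's (theta1, theta2, p0).
    """
    if profiles is None:
        profiles = generate_profiles(config)
    rng = _rng(config, 1)
    if not profiles:
        df = pd.DataFrame(columns=[config.observation_end_year]).astype("Int64")
        df.index.name = "child_id"
        return StatusPanel(statuses=df, observation_end_year=config.observation_end_year)

    min_year = min(p.birth_year for p in profiles)
    all_years = list(range(min_year, config.observation_end_year + 1))
    groups: dict[tuple[str, int], list[str]] = {}
    for p in profiles:
        groups.setdefault((p.child_type, p.birth_year), []).append(p.child_id)

    frames = []
    for (ctype, cohort) in sorted(groups):
        ids = groups[(ctype, cohort)]
        n_years = config.observation_end_year - cohort + 1
        t1, t2 = config.theta(ctype, cohort)
        paths = simulate_status_matrix(len(ids), n_years, t1, t2,
                                       config.p0(ctype, cohort), rng)
        block = pd.DataFrame(
            paths, index=ids, columns=list(range(cohort, config.observation_end_year + 1))
        )
        frames.append(block)
    df = pd.concat(frames).reindex(columns=all_years).astype("Int64")
    df = df.loc[[p.child_id for p in profiles]]
    df.index.name = "child_id"
    return StatusPanel(statuses=df, observation_end_year=config.observation_end_year)


def _doy_date(year: int, doy: int) -> date:
    return date(year, 1, 1) + timedelta(days=doy - 1)


def render_events(
    panel: StatusPanel, config: SimConfig
) -> list[MovementEvent]:
    """Render a status panel as a plausible border-crossing event stream.

    For every returned (status 1) year a child gets stays totalling at least
    31 nights inside one half-year window; for not-returned years, no events
    or a short visit capped below the threshold. Specifically:

    * default returned-year rendering: one stay of 34–100 nights starting
      mid-January to end-February (all nights inside the first half-year);
    * with probability ``scattered_prob`` the stay is instead four separate
      9–12 night visits spread across the first half-year (non-consecutive
      nights totalling 36+);
    * a child returned in their birth year is, with probability
      ``born_resident_prob``, rendered as already resident: their record opens
      with a departure in March–June (presence since the start of the year);
    * two consecutive returned years become, with probability
      ``persist_prob``, one residence spell from 1 December to early February
      or March — 31 December nights in the earlier year, 35+ January/February
      nights in the later one — so intervals straddle New Year; if the later
      year is the last observed one the closing departure may be omitted,
      leaving a stay open at the observation end;
    * a not-returned year shows, with probability ``visit_prob``, one visit of
      1–20 nights in the second half-year.

    The construction guarantees that classification at the default 31-night
    threshold reproduces the panel exactly.
    """
    rng = _rng(config, 2)
    events: list[MovementEvent] = []
    order = 0

    def emit(child: str, when: date, direction: Direction) -> None:
        nonlocal order
        order += 1
        events.append(MovementEvent(child, when, direction, source_order=order))

    end_year = panel.observation_end_year
    for child_id, row in panel.statuses.iterrows():
        observed = [int(y) for y in panel.years if not pd.isna(row[y])]
        if not observed:
            continue
        birth_year = observed[0]
        carried_in = False
        for y in observed:
            status = int(row[y])
            if status == 1:
                if not carried_in:
                    if y == birth_year and rng.random() < config.born_resident_prob:
                        # Already living in Hong Kong: record opens with a
                        # departure; presence runs from 1 January.
                        emit(child_id, _doy_date(y, int(rng.integers(60, 171))),
                             Direction.DEPARTURE)
                    elif rng.random() < config.scattered_prob:
                        for k in range(4):
                            start = 10 + 40 * k + int(rng.integers(0, 9))
                            length = int(rng.integers(9, 13))
                            emit(child_id, _doy_date(y, start), Direction.ARRIVAL)
                            emit(child_id, _doy_date(y, start + length),
                                 Direction.DEPARTURE)
                    else:
                        a = int(rng.integers(15, 61))
                        length = int(rng.integers(34, 101))
                        emit(child_id, _doy_date(y, a), Direction.ARRIVAL)
                        emit(child_id, _doy_date(y, a + length), Direction.DEPARTURE)
                carried_in = False
                next_returned = y < observed[-1] and int(row[y + 1]) == 1
                if next_returned and rng.random() < config.persist_prob:
                    # Residence spell across New Year: 31 December nights now,
                    # 35+ January/February nights next year.
                    emit(child_id, date(y, 12, 1), Direction.ARRIVAL)
                    emit(child_id, _doy_date(y + 1, int(rng.integers(36, 71))),
                         Direction.DEPARTURE)
                    carried_in = True
                elif y == end_year == observed[-1] and rng.random() < config.persist_prob:
                    # Still resident when observation ends: arrival never
                    # matched by a departure.
                    emit(child_id, date(y, 12, 1), Direction.ARRIVAL)
            else:
                carried_in = False
                if rng.random() < config.visit_prob:
                    a = int(rng.integers(190, 321))
                    length = int(rng.integers(1, 21))
                    emit(child_id, _doy_date(y, a), Direction.ARRIVAL)
                    emit(child_id, _doy_date(y, a + length), Direction.DEPARTURE)
    events.sort(key=lambda e: (e.child_id, e.date, e.source_order))
    return events
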