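"""Two-state Markov model of yearly return status.

Each child's returned status Y_n in {0, 1} at age n is modelled as a
homogeneous two-state discrete-time Markov chain with cohort-specific
transition matrix

    [[ theta1, 1 - theta1 ],
     [ 1 - theta2, theta2 ]]

where theta1 = Pr(stay not-returned | not-returned last year) and
theta2 = Pr(stay returned | returned last year). Transition probabilities
are estimated by maximum likelihood from the observed year-to-year status
transitions, pooled over children and ages within a birth cohort. The
marginal probability of being returned evolves as

    p_{t+1} = p_t * theta2 + (1 - p_t) * (1 - theta1)

and converges geometrically, at rate |theta1 + theta2 - 1| per year, to the
stationary limit p* = (1 - theta1) / ((1 - theta1) + (1 - theta2)) whenever
the chain is not doubly absorbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .movement import ChildProfile, StatusPanel

__all__ = [
    "TransitionCounts",
    "TransitionMatrix",
    "ProjectionResult",
    "ReturneeAggregate",
    "count_transitions",
    "estimate_theta",
    "fit_cohorts",
    "project",
    "initialize_from_panel",
    "aggregate_returnees",
]


@dataclass(frozen=True)
class TransitionCounts:
    """Sufficient statistics for one cohort: observed year-pair transitions.

    ``nab`` counts transitions from state ``a`` to state ``b``, pooled over
    children and ages. The total equals the number of observed consecutive
    year pairs: sum over children of (observed years - 1).
    """

    cohort: int
    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        if min(self.n00, self.n01, self.n10, self.n11) < 0:
            raise ValueError("transition counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def from0(self) -> int:
        return self.n00 + self.n01

    @property
    def from1(self) -> int:
        return self.n10 + self.n11


@dataclass(frozen=True)
class TransitionMatrix:
    """Estimated cohort transition matrix (theta1, theta2) with Wald intervals.

    A row with zero exposure (no transitions out of that state observed)
    leaves the corresponding theta inestimable: the value is ``None`` and the
    flag is set. Confidence intervals are Wald binomial intervals, clipped to
    [0, 1]; the model itself carries no sampling-error statement, so the
    intervals are reporting tooling only.
    """

    cohort: int
    theta1: float | None
    theta2: float | None
    n_from0: int = 0
    n_from1: int = 0
    theta1_ci: tuple[float, float] | None = None
    theta2_ci: tuple[float, float] | None = None

    @property
    def estimable(self) -> bool:
        return self.theta1 is not None and self.theta2 is not None

    def matrix(self) -> np.ndarray:
        """The 2x2 row-stochastic matrix; raises if either row is inestimable."""
        if not self.estimable:
            raise ValueError(
                f"cohort {self.cohort}: transition matrix not fully estimable "
                f"(theta1={self.theta1}, theta2={self.theta2}); consider pooling "
                f"adjacent cohorts or supplying a prior"
            )
        return np.array(
            [[self.theta1, 1.0 - self.theta1], [1.0 - self.theta2, self.theta2]]
        )

    @property
    def stationary(self) -> float | None:
        """Long-run returned probability (1-theta1)/((1-theta1)+(1-theta2)),
        or ``None`` for the degenerate doubly-absorbing chain theta1=theta2=1."""
        if not self.estimable:
            return None
        denom = (1.0 - self.theta1) + (1.0 - self.theta2)
        if denom == 0.0:
            return None
        return (1.0 - self.theta1) / denom


@dataclass(frozen=True)
class ProjectionResult:
    """Projected returned probabilities for one cohort.

    ``years`` run from the initialization year to the horizon; ``p`` holds the
    matching probabilities, with ``p[0]`` the initial state distribution.
    """

    cohort: int
    years: tuple[int, ...]
    p: tuple[float, ...]
    stationary: float | None

    def at_year(self, year: int) -> float:
        try:
            return self.p[self.years.index(year)]
        except ValueError:
            raise KeyError(f"cohort {self.cohort}: year {year} not projected") from None

    def at_age(self, age: int) -> float:
        return self.at_year(self.cohort + age)


@dataclass(frozen=True)
class ReturneeAggregate:
    """Expected number of returnees across cohorts at a target age."""

    target_age: int
    by_cohort: Mapping[int, float]  # cohort -> N_j * p_j
    scenario: str = "projected"

    @property
    def total(self) -> float:
        return float(sum(self.by_cohort.values()))


def _wald_ci(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    p = k / n
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def count_transitions(
    panel: StatusPanel, profiles: Sequence[ChildProfile], cohort: int
) -> TransitionCounts:
    """Tally year-to-year status transitions of one birth cohort.

    Each child contributes one transition per consecutive observed year pair,
    from birth year through the panel's last year. Requires at least two
    observed years for the cohort.
    """
    ids = [p.child_id for p in profiles if p.birth_year == cohort]
    if not ids:
        raise ValueError(f"no children in cohort {cohort}")
    mat, years = panel.cohort_matrix(ids, cohort)
    if len(years) < 2:
        raise ValueError(
            f"cohort {cohort}: need at least 2 observed years, have {len(years)}"
        )
    prev, nxt = mat[:, :-1], mat[:, 1:]
    n00 = int(np.sum((prev == 0) & (nxt == 0)))
    n01 = int(np.sum((prev == 0) & (nxt == 1)))
    n10 = int(np.sum((prev == 1) & (nxt == 0)))
    n11 = int(np.sum((prev == 1) & (nxt == 1)))
    return TransitionCounts(cohort, n00, n01, n10, n11)


def estimate_theta(counts: TransitionCounts) -> TransitionMatrix:
    """Maximum-likelihood transition probabilities from pooled counts.

    For a homogeneous chain the MLE is the row-wise empirical fraction:
    theta1 = n00/(n00+n01), theta2 = n11/(n10+n11). A row without exposure is
    flagged inestimable rather than imputed; if neither row has exposure the
    cohort carries no information and an error is raised.
    """
    if counts.total == 0:
        raise ValueError(f"cohort {counts.cohort}: no observed transitions")
    theta1 = counts.n00 / counts.from0 if counts.from0 > 0 else None
    theta2 = counts.n11 / counts.from1 if counts.from1 > 0 else None
    return TransitionMatrix(
        cohort=counts.cohort,
        theta1=theta1,
        theta2=theta2,
        n_from0=counts.from0,
        n_from1=counts.from1,
        theta1_ci=_wald_ci(counts.n00, counts.from0) if counts.from0 > 0 else None,
        theta2_ci=_wald_ci(counts.n11, counts.from1) if counts.from1 > 0 else None,
    )


def fit_cohorts(
    panel: StatusPanel,
    profiles: Sequence[ChildProfile],
    child_type: str | None = None,
) -> dict[int, TransitionMatrix]:
    """Fit one transition matrix per birth cohort (optionally one child type).

    Cohorts observed for fewer than two years are skipped.
    """
    pool = [p for p in profiles if child_type is None or p.child_type == child_type]
    out: dict[int, TransitionMatrix] = {}
    for cohort in sorted({p.birth_year for p in pool}):
        if panel.observation_end_year - cohort < 1:
            continue
        out[cohort] = estimate_theta(count_transitions(panel, pool, cohort))
    return out


def project(
    matrix: TransitionMatrix,
    p0: float,
    steps: int,
    start_year: int | None = None,
) -> ProjectionResult:
    """Iterate the marginal returned probability ``steps`` years forward.

    p_{t+1} = p_t * theta2 + (1 - p_t) * (1 - theta1); the result equals the
    second component of (1-p0, p0) times the t-step matrix power. The first
    entry of the result is p0 itself. ``start_year`` defaults to the cohort
    (so entries align with age).
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    if steps < 0:
        raise ValueError("steps must be nonnegative")
    if not matrix.estimable:
        raise ValueError(
            f"cohort {matrix.cohort}: cannot project with inestimable "
            f"transition probabilities; pool adjacent cohorts or supply a prior"
        )
    if start_year is None:
        start_year = matrix.cohort
    path = [p0]
    p = p0
    for _ in range(steps):
        p = p * matrix.theta2 + (1.0 - p) * (1.0 - matrix.theta1)
        path.append(p)
    return ProjectionResult(
        cohort=matrix.cohort,
        years=tuple(range(start_year, start_year + steps + 1)),
        p=tuple(path),
        stationary=matrix.stationary,
    )


def initialize_from_panel(
    panel: StatusPanel, profiles: Sequence[ChildProfile], cohort: int, year: int
) -> float:
    """Observed fraction of the cohort in the returned state at ``year``.

    This is the natural projection starting point: the empirical state
    distribution at the last observed year. Equals the cohort return rate
    divided by 100.
    """
    ids = [p.child_id for p in profiles if p.birth_year == cohort]
    if not ids:
        raise ValueError(f"no children in cohort {cohort}")
    if year < cohort or year not in panel.years:
        raise ValueError(f"year {year} not observed for cohort {cohort}")
    col = panel.statuses.loc[ids, year]
    return float(col.sum()) / len(ids)


def aggregate_returnees(
    cohort_sizes: Mapping[int, int],
    projections: Mapping[int, ProjectionResult],
    target_age: int,
    scenario: str = "projected",
    rate_override: Mapping[int, float] | None = None,
) -> ReturneeAggregate:
    """Expected returnees summed over cohorts when each reaches ``target_age``.

    For each cohort j the contribution is N_j * p_{j, target age}, taking the
    probability from the cohort's projection, or from ``rate_override``
    (probabilities in [0, 1]) for counterfactual scenario comparisons such as
    survey-based official rates.
    """
    by_cohort: dict[int, float] = {}
    for cohort, n in cohort_sizes.items():
        if rate_override is not None and cohort in rate_override:
            p = rate_override[cohort]
        else:
            if cohort not in projections:
                raise ValueError(f"no projection for cohort {cohort}")
            p = projections[cohort].at_age(target_age)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"cohort {cohort}: probability {p} outside [0, 1]")
        by_cohort[cohort] = n * p
    return ReturneeAggregate(target_age=target_age, by_cohort=by_cohort, scenario=scenario)
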