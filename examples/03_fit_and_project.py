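"""Fitting the two-state chain and projecting return rates forward.

Estimates cohort transition probabilities from a synthetic status panel,
projects the returned probability to 2030 starting from the last observed
year, and aggregates expected returnees at age 21.
"""

from hkreturns import (
    SimConfig,
    aggregate_returnees,
    count_transitions,
    estimate_theta,
    generate_profiles,
    generate_status_paths,
    initialize_from_panel,
    project,
)

cfg = SimConfig(cohort_sizes={2006: 1000, 2009: 1000}, observation_end_year=2016,
                seed=21, type_a_share=0.0)  # type B children only
profiles = generate_profiles(cfg)
panel = generate_status_paths(cfg, profiles)

projections = {}
sizes = {}
for cohort in (2006, 2009):
    counts = count_transitions(panel, profiles, cohort)
    tm = estimate_theta(counts)
    lo1, hi1 = tm.theta1_ci
    lo2, hi2 = tm.theta2_ci
    print(f"cohort {cohort}: theta1={tm.theta1:.3f} [{lo1:.3f}, {hi1:.3f}]  "
          f"theta2={tm.theta2:.3f} [{lo2:.3f}, {hi2:.3f}]")
    # theta1: P(stay away | away last year); theta2: P(stay | returned last
    # year). The generator used (0.92, 0.85), so estimates should be close.

    p0 = initialize_from_panel(panel, profiles, cohort, 2016)
    res = project(tm, p0, steps=2030 - 2016, start_year=2016)
    projections[cohort] = res
    sizes[cohort] = sum(1 for p in profiles if p.birth_year == cohort)
    print(f"  observed 2016 rate {100 * p0:.1f}% -> projected 2030 rate "
          f"{100 * res.at_year(2030):.1f}%  (long-run limit "
          f"{100 * res.stationary:.1f}%)")

agg = aggregate_returnees(sizes, projections, target_age=21)
print(f"\nexpected returnees at age 21: {agg.total:.0f} of {sum(sizes.values())}")
# Each cohort contributes N_j * p_j(age 21); the projection converges
# geometrically to (1-theta1)/((1-theta1)+(1-theta2)).
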