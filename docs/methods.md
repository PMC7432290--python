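# Methods

## Problem and data model

The population of interest is children born in Hong Kong to Mainland
Chinese parents — type A (father a Hong Kong resident) and type B (neither
parent a resident). They hold permanent residency but mostly grow up on the
Mainland; the planning question is how many will be living in Hong Kong at
each future age. The observable record is the stream of their border
crossings: one row per crossing with child id, date, and direction
(arrival into or departure out of Hong Kong), plus a registration profile
per child (birth year, child type, parents' education levels coded 0 =
no schooling/kindergarten, 1 = primary, 2 = secondary/matriculation, 3 =
tertiary non-degree, 4 = tertiary degree, X = unknown).

## Residence classification

A child is **returned** in calendar year *t* if they spent at least 31
nights, not necessarily consecutive, in Hong Kong within either half of the
year (1 Jan–30 Jun or 1 Jul–31 Dec). This is the official census
definition of residence for this population and the package's default
(`night_threshold = 31`, configurable).

Events are reduced to maximal half-open presence intervals `[start, end)`:

- **Same-day pairs.** When a child has both an arrival and a departure on
  one day, the arrival is assumed first. A same-day round trip therefore
  covers zero nights.
- **Night attribution.** A night belongs to the date on which it begins, so
  `[start, end)` contributes the nights of `start` through `end − 1 day`.
  With half-open windows this makes night counts additive across window
  boundaries: H1 nights + H2 nights = year nights, exactly.
- **Open boundaries.** A record opening with a departure means the child was
  already living in Hong Kong: presence is imputed from the start of their
  observation period (`open_start`). A record ending with an arrival
  yields presence through the end of observation (`open_end`). Each child's
  period starts at the later of the study start and 1 Jan of their birth
  year, and ends 1 Jan after the last observed year (exclusive).
- **Malformed sequences.** Consecutive arrivals (or departures) without the
  opposite event in between are collapsed onto the first, with a logged
  data-quality warning; collapsing is the conservative repair that keeps
  intervals well formed. Events out of date order are an error, not a
  repair.
- **Birth-year exposure.** A child born mid-year is classified over the
  full-year windows like anyone else — one uniform rule, no exposure
  adjustment.

The per-year statuses form the **status panel**: one 0/1 cell per child per
year from birth year to the observation end (missing before birth).

## Return-rate tables

The noncumulative return rate of cohort *j* in year *t* is
100 × (returned cohort-*j* children in *t*) / (cohort-*j* children), with
the denominator attached to every cell. Stratified tables condition the
denominator on child type and a parental education level. Cells with an
empty denominator are *absent*, never 0%; denominators below 30 are flagged
unstable rather than suppressed, because tiny strata (e.g. mothers with no
schooling) swing wildly between years. Rates are exact internally; rounding
to one decimal (rates) or two decimals (birth-count shares) happens only at
presentation. The unstratified rate is algebraically the denominator-
weighted mean of the stratum rates, and the test suite checks this to
1e−9.

## The two-state chain

Status at age *n + 1* is assumed to depend only on status at age *n*, with
transition matrix rows (θ₁, 1 − θ₁) and (1 − θ₂, θ₂), constant over ages
within a birth cohort but free across cohorts (and fitted separately by
child type in the pipeline, since type A and B children behave very
differently). The estimator is the pooled maximum likelihood:
θ̂₁ = n₀₀/(n₀₀ + n₀₁), θ̂₂ = n₁₁/(n₁₀ + n₁₁), where n&#8336;&#8338; counts observed
year-pair transitions over all children and ages of the cohort. Pooling
over ages is what homogeneity licenses; no age weighting is applied.

- **Inestimable rows.** A cohort with no observed exposure in a state (e.g.
  nobody ever returned) leaves that θ flagged inestimable. Projection then
  refuses with advice to pool adjacent cohorts or supply a prior — never a
  silent imputation.
- **Uncertainty.** Wald 95% binomial intervals on each θ̂ are reported as
  additive tooling; the model itself makes no sampling-error statement. At
  the transition counts this design produces (thousands per cohort), Wald
  coverage is nominal; the acceptance study verifies coverage within
  [0.92, 0.98] at 200 replicates.

**Projection.** p&#8348;₊₁ = p&#8348;θ₂ + (1 − p&#8348;)(1 − θ₁), equal to the matrix-power
form (1 − p₀, p₀)·Mᵗ. The error to the stationary limit
p\* = (1 − θ₁)/((1 − θ₁) + (1 − θ₂)) contracts by exactly |θ₁ + θ₂ − 1| per
step. By default projections start from the empirical state distribution at
the last observed year (the natural record-based choice); starting from
birth (p₀ at age 0) is available by passing that probability instead.
Aggregates are Σ&#8345; N&#8345;·p&#8345;(target age), with an optional per-cohort scenario
rate map for counterfactual comparisons against survey-based official
projections.

## Synthetic populations

The generator emulates the structure of the confidential records, not their
microstructure. Defaults define the study conditions and were chosen once:

- Cohorts and sizes are caller-specified; type A share defaults to 0.25 of
  study children. Education distributions default to a plausible profile
  with type B parents better educated than type A (mode at secondary
  level, small no-schooling and unknown shares); the real marginals are
  unpublished.
- Chain parameters default to (θ₁, θ₂) = (0.50, 0.90) for type A with birth
  state p₀ = 0.6, and (0.92, 0.85) for type B with p₀ = 0.1 — high, fast
  return for type A, low and slow for type B, consistent with the observed
  contrast between the two groups. Both are overridable per (type, cohort).
- Status paths are simulated vectorised per (type, cohort) group from a
  single seeded generator; profiles, paths and events use independent
  substreams of the config seed, so each stage is reproducible alone.

**Event rendering** inverts the classifier: a returned year gets one
34–100-night stay inside the first half-year (or, with `scattered_prob`,
four separate 9–12-night visits — exercising the "not necessarily
consecutive" clause); a not-returned year gets nothing or, with
`visit_prob`, one 1–20-night visit in the second half-year. With
`persist_prob`, consecutive returned years merge into a residence spell
crossing New Year (31 December nights + 35–69 January/February nights), and
a child returned in their birth year may enter the record as already
resident (leading departure). The construction guarantees the round trip —
classify(render(panel)) = panel — at the default 31-night threshold; the
guarantee is specific to that threshold. The generator makes no attempt to
match real visit-frequency patterns (day trippers, cross-border schooling),
so passing tests certify the pipeline's logic, not distributional realism
of any real cohort.

## Numerical and scale choices

- All probabilities are exact double arithmetic; no tolerance tuning is
  needed anywhere in the core (recursion vs. matrix power agrees to ~1e−15;
  geometric contraction is exact to rounding).
- Night counting is integer date arithmetic on half-open intervals; the
  brute-force date-iteration oracle in the tests is the independent check.
- Problem sizes: property tests run on event streams of ≤ 20 events;
  round-trip checks on 1,000 children × 12 years; the estimator-recovery
  study on 200 replicates of 2,000 children × 12 years per setting. These
  sizes put Monte-Carlo error well below the tolerances being checked while
  keeping the whole suite fast.
- Seeds: every simulation takes an explicit integer seed; library defaults
  are documented in the dataclasses, and the pipeline derives all streams
  from the one seed in its run config, making reruns byte-identical.

## Limitations

- Direction is binary in/out of Hong Kong; travel to destinations other
  than the Mainland is indistinguishable, and identities are taken as
  given (no record linkage or de-duplication).
- The chain is first-order and age-homogeneous within cohort; no
  covariate-dependent transitions (education enters only through stratified
  refits), no seasonality below the yearly step.
- Projections inherit the estimation window: cohorts observed only briefly
  yield wide intervals, and recent tiny cohorts (post-2012 type B) are
  dominated by small-sample noise — the small-cell flags exist for exactly
  this case.
- Published headline projections for the real cohorts cannot be reproduced
  without the confidential microdata; the package validates its machinery
  on synthetic populations instead.
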