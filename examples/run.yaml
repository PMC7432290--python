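# Demo run configuration for `hkreturns run-all`.
out_dir: scratch/run-all-demo
seed: 42
night_threshold: 31
horizon_year: 2030
target_age: 21
stratify_by: none
sim:
  cohort_sizes:
    2005: 500
    2008: 500
  observation_end_year: 2016
  type_a_share: 0.25
# Survey-style flat scenario for the planning comparison (probability of
# being returned at the target age, per cohort):
scenario_rates:
  2005: 0.5
  2008: 0.5
scenario_label: survey-based
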