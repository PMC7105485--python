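# Demo pipeline configuration: 2000-sample synthetic cohort, all stages.
ethnicity: east_asian
n_cases: 700
n_controls: 1300
prevalence: 0.01
seed: 42
stages:
  - simulate
  - assoc
  - condition
  - meta
  - interact
  - credible
  - score
  - serology
  - crs
  - diagnose
out_dir: results/demo
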