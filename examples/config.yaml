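# Full-pipeline configuration: default study-structure cohort with a 5%
# screening-violation rate so the eligibility funnel has work to do.
seed: 7
output_dir: nextri_out
generator:
  screen_violation_rate: 0.05
screening: {}
fit:
  target_edf: 5.0
partition_candidates:
  - [sex]
  - [age, 50]
age_cut: 50
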