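# Full pipeline on a simulated treatment-arm cohort.
# Replace `simulate` with an `inputs` block (events/enrollment/covariates CSVs)
# to run on real log files.
seed: 1
simulate:
  arm: webquit
  n_users: 1240
smoothing:
  bandwidth_days: 28
fpca:
  fve_threshold: 0.90
  max_components: 10
cluster:
  k: auto
  k_max: 5
  threshold: 0.85
  n_splits: 20
association:
  outcome: abstinent
  mode: complete_case
  candidates: [age, male, smoked_gt_10_years, half_pack_or_more, commitment,
               depression, anxiety, panic, ptsd]
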