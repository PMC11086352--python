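# A reduced end-to-end run: 4 subjects, one side, one scale task.
cohort:
  n_subjects: 4
  age_groups: {s01: under30, s02: under30, s03: over50, s04: over50}
  expertise: {s01: junior, s02: senior, s03: junior, s04: senior}
  tasks: [scale_cmaj]
  sides: [L]
  n_synergies_true: 2
  duration_s: 6.0
  fs: 50.0
preprocess: {}
factorize:
  n_nmf_reps: 8
  n_keep: 3
  max_iter: 200
  tol: 1.0e-7
  max_M: 4
cluster:
  k_range: [2, 5]
  n_outer: 10
  n_rep: 10
stats:
  min_pairs: 4
master_seed: 7
output_root: emgsynergy_run
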