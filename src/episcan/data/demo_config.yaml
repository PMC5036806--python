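# Demo pipeline: a small simulated RIL study with one planted epistatic pair
# shared by three environments.  Runs in seconds; the planted pair
# (Mark00004 x Mark00014) should come out significant and stable.
seed: 20160926
out_dir: demo_out
simulate:
  n_lines: 147
  map:
    n_markers: 30
    n_groups: 3
    length_cm: 240.0
  environments: [ENV1, ENV2, ENV3]
  grand_mean: 20.0
  residual_sd: 0.5
  het_rate: 0.002
  missing_rate: 0.0
  additive: []
  epistatic:
    - {marker_a: Mark00004, marker_b: Mark00014, w: 0.8}
  env_shifts:
    ENV2: 0.5
    ENV3: -0.3
scan:
  alpha_base: 0.001
  threshold_mode: ordered
  chunk_size: 100000
  k: 10
  reps: 10
  cv: significant
stability:
  preset: half
epistasis:
  alpha2: 0.01
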