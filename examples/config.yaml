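# Full pipeline configuration for `sdqmap run --config examples/config.yaml`.
# Defaults emulate the study conditions (~35k children, 21 wards, 180
# preschools, 8 cohorts); this example is scaled down to run in a couple of
# minutes on one CPU.
out_dir: run_example
seeds:
  simulate: 1
  fit_dm: 2
  fit_ml: 3
  diagnose: 4
geography:
  n_wards: 21
  layout: voronoi
population:
  n_children: 5000
  n_preschools: 60
inference:
  chains: 2
  warmup: 800
  draws: 800
forward_build: true               # DIC-driven term selection, both models
always_participating_only: true   # sensitivity: preschools in all cohorts
median_outcome_dm: true           # sensitivity: Gaussian median-score model
render_maps: true
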