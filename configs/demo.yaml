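# Demonstration run: simulate the default three-group cohort (32 BVP / 43
# PPPD / 32 HC), score every participant and run the statistical battery.
geometry:
  wall_distance_cm: 192.0
  horizontal_spacing_cm: 51.4
  vertical_spacing_cm: 51.4
scoring:
  calibration_threshold_deg: 10.0
simulation:
  group_sizes: {BVP: 32, PPPD: 43, HC: 32}
  repeats: 1
  master_seed: 0
statistics:
  alpha: 0.05
  levene_alpha: 0.05
  posthoc: bootstrap-tukey
  n_boot: 1000
  seed: 0
paths:
  output_dir: rwpt_output
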