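# Canonical pipeline configuration (defaults shown; any key may be omitted).
# Run with:  spadflim pipeline --config docs/example_config.yaml
grid:
  n_bins: 300
  bin_width_ns: 0.04
irf:
  fwhm_ns: 0.23
  peak_bin: 50
dataset:
  n_samples: 50000
  val_fraction: 0.2
  tau_range_ns: [0.1, 5.0]
  nt_range: [100.0, 10000.0]
array:
  n_rows: 192
  n_cols: 128
  peak_jitter_span_ns: 4.0
  hot_pixel_fraction: 0.01
  hot_pixel_rate_multiplier: 100.0
  dark_rate_per_bin: 4.07e-5
train:
  epochs: 100
  batch_size: 128
  learning_rate: 1.0e-4
  w_bits: 1
  a_bits: 4
cmm:
  window_start_bin: 50
  window_end_bin: 300
evaluation:
  n_test: 2000
  n_nt_bins: 20
  event_threshold_pc: 400.0
seed: 0
output_dir: spadflim_run
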