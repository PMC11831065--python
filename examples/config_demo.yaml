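# Demo pipeline configuration: planted-deficit cohort at desk scale.
# Run with:  neurocoh run --config examples/config_demo.yaml --out demo_out
seed: 0
simulate:
  preset: demo        # or "null" for an exchangeable-groups cohort
  n_per_group: 12
preprocess:
  highpass: 0.5       # Hz
  lowpass: 35.0       # Hz
  kurtosis_z_threshold: 5.0
  discard_lead_s: 4.0
  epoch_s: 56.0
welch:
  segment_s: 2.0      # -> 0.5 Hz resolution, resolves all band edges
  overlap_fraction: 0.5
  window: hann
  detrend: constant
thresholds: [0.5, 0.7]
q_cutoff: 0.05
out_dir: demo_out
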