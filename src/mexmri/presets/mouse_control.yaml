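# Vehicle-injected mouse group (8 weeks).
species: mouse
group: control
schedule: mouse
F: {mean: 0.042, sd: 0.006}
T1_ms: {mean: 1436.0, sd: 54.0}
tau_ms: {mean: 20.0, sd: 0.0}
suppression_range: [0.982, 0.996]
histology:
  stain: MT
  slope: 175.35
  intercept: -6.792
  group_percent: 0.573   # group-mean staining %
  noise_sd: 0.3
inflammation_scores: [0]
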