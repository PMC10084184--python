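# CCl4-treated mouse group (8 weeks).
species: mouse
group: fibrosis
schedule: mouse
F: {mean: 0.062, sd: 0.006}
T1_ms: {mean: 1485.0, sd: 160.0}
tau_ms: {mean: 20.0, sd: 0.0}
suppression_range: [0.982, 0.996]
histology:
  stain: MT
  slope: 175.35
  intercept: -6.792
  group_percent: 4.08   # group-mean staining %
  noise_sd: 0.3
inflammation_scores: [1, 2]
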