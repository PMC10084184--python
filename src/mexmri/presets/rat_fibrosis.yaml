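# CCl4-treated rat group (6-week timepoint).
species: rat
group: fibrosis
schedule: rat
F: {mean: 0.10, sd: 0.02}
T1_ms: {mean: 1840.0, sd: 200.0}
tau_ms: {mean: 20.0, sd: 0.0}
suppression_range: [0.979, 0.994]
histology:
  stain: PSR
  slope: 346.08
  intercept: -26.20
  group_percent: 11.87   # group-mean staining %
  noise_sd: 0.5
inflammation_scores: [1, 2]
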