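# Vehicle-injected rat group (6-week timepoint).
species: rat
group: control
schedule: rat
F: {mean: 0.080, sd: 0.003}
T1_ms: {mean: 1481.0, sd: 177.0}
tau_ms: {mean: 20.0, sd: 0.0}
suppression_range: [0.979, 0.994]
histology:
  stain: PSR
  slope: 346.08        # histology % per unit F (two-point solve on group means)
  intercept: -26.20    # % ; negative: the regression does not cross the origin
  group_percent: 1.972   # group-mean staining %
  noise_sd: 0.5
inflammation_scores: [0]
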