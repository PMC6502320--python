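# Calibrated six-stratum scenario: expected list sizes ~3824/~2594,
# overlap ~856, captured-list demographics matching the published
# surveillance marginals (see docs/methods.md for the calibration).
true_N: 11557
classes:
- label: <=84
  proportion: 0.545083
  female_fraction: 0.646743
  age_mean: 84.5
  age_sd: 8.557
  age_lo: 40.0
  age_hi: 85.0
  pA: 0.10618
  pB: 0.225208
- label: 85-89
  proportion: 0.38
  female_fraction: 0.787255
  age_mean: 87.0
  age_sd: 3.0
  age_lo: 85.0
  age_hi: 90.0
  pA: 0.60014
  pB: 0.225208
- label: '>=90'
  proportion: 0.074917
  female_fraction: 0.781568
  age_mean: 92.0
  age_sd: 3.5
  age_lo: 90.0
  age_hi: 110.0
  pA: 0.60014
  pB: 0.215208
delta: 0.0
duplicate_rate: 0.0
seed: 0
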