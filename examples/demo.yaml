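# Shipped demo: a 60-day synthetic winter with the default five-regime mix.
scenario:
  n_days: 60
  seed: 1234
attribution:
  fraction_mode: cwt     # Fig-2b-style concentration-weighted fractions
  label_mode: count      # daily origin labels from residence fractions
health:
  beta: 0.38
  beta_min: 0.31
  beta_max: 0.45
  beta_scale: 100.0      # beta read as per 100 ug/m3 -> beta_eff = 0.0038
  c0: 0.0
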