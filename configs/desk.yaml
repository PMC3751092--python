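# Scaled-down single-cell profile: the headline-check conditions.
cohort:
  n: 5000
  age_min: 40.0
  age_max: 69.0
  female_prevalence: 0.59
  wave_gap: 13.0
events:
  true_hr: 1.5
  profile: high_incidence
missingness:
  mechanism: CDMAR_ENH
  prop: 0.50
mi:
  m: 5
experiment:
  nsim: 200
  nsim_reference: 500
  master_seed: 0
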