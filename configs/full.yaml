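# Full-scale study conditions (hours of runtime on one CPU).
cohort:
  n: 41476
events:
  true_hr: 1.5
  profile: default
missingness:
  mechanism: CDMAR_ENH
  prop: 0.50
mi:
  m: 20
experiment:
  nsim: 1000
  nsim_reference: 10000
  master_seed: 0
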