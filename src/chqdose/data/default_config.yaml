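ontogeny:
  cyp3a4:
    f_birth: 0.11
    age50_years: 0.64
    hill: 1.91
  cyp2c8:
    f_birth: 0.15
    age50_years: 0.6
    hill: 1.2
  gfr:
    pma50_weeks: 47.7
    hill: 3.4
    term_pma_weeks: 40.0
compound:
  fm_cyp3a4: 0.15
  fm_cyp2c8: 0.2
  f_renal: 0.56
  f_other: 0.09
  cl_adult: 24.22
  vss_per_kg: 150.0
  v1_fraction: 0.1
  q_inter: 200.0
  ka: 0.5
  f_bioavail: 0.8
  t_half_terminal_target: 14.0
population:
  weight_cv: 0.15
  growth_table_path: null
  prop_female: 0.5
regimen:
  cap_mg: 3300.0
  loading_interval_h: 12.0
simulation:
  duration_days: 70.0
  grid_step_h: 2.0
  auc_window_h: null
  sem_mode: between_trial
  paired_verification: true
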