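# Oncosimulator parameter ranges and proliferation targets, NSCLC scenario.
# prolif_rate is ln2 / 70 h (metabolic proliferation time 70 h); the sampled
# T_c upper end is additionally capped at ln2/a during cohort generation.
sample:
  T_c: [20.0, 134.0]
  T_G0: [96.0, 240.0]
  T_N: [1.0, 100.0]
  T_A: [1.0, 25.0]
  N_LIMP: [13, 24]
  R_A: [0.0, 0.001]
  R_ADiff: [0.0001, 0.02]
  P_G0toG1: [0.0, 0.2]
fixed:
  alpha: 0.35
  beta: 0.035
targets:
  T_d_days: 370.0
  GF: 0.23
  prolif_rate: 0.009902
bounds:
  stem_living: [1.0e-5, 2.5e-4]
  necrotic_total_max: 0.30
  apoptotic_total_max: 0.05
  p_sym_max: 0.3
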