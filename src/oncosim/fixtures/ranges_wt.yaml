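# Oncosimulator parameter ranges, Wilms-tumor scenario.  Targets T_d/GF and
# prolif_rate vary per proliferation profile; the values below are the
# central profile (T_d 25 d, GF 25%, proliferation time 20 h).
sample:
  T_c: [11.0, 50.0]
  T_G0: [96.0, 240.0]
  T_N: [1.0, 200.0]
  T_A: [1.0, 25.0]
  N_LIMP: [13, 24]
  R_A: [0.0, 0.001]
  R_ADiff: [0.0, 0.02]
  P_G0toG1: [0.0, 0.2]
fixed:
  alpha: 0.35
  beta: 0.035
targets:
  T_d_days: 25.0
  GF: 0.25
  prolif_rate: 0.034657
bounds:
  stem_living: [1.0e-5, 2.5e-4]
  necrotic_total_max: 1.0
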