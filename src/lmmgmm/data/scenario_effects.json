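{
  "comment": "Default simulation effect sizes. Calibrated once so the associative components explain ~57% of var(Y) (total signal variance 2.65 against residual variance 2.0), the share implied by a near-oracle Pearson correlation of ~0.76 at 3 associative regions. Scenario II reallocates the same total signal budget across the active layers of each disease model.",
  "sigma0_sq": 2.0,
  "signal_variance": 2.65,
  "scenario_I": {
    "gamma_expr": 2.0,
    "sigma_g_sq": 0.275,
    "sigma_m_sq": 0.275,
    "sigma_gm_sq": 0.0
  },
  "scenario_II": {
    "S1_E":        {"gamma_expr": 3.255764, "sigma_g_sq": 0.0,      "sigma_m_sq": 0.0,      "sigma_gm_sq": 0.0},
    "S2_G":        {"gamma_expr": 0.0,      "sigma_g_sq": 0.883333, "sigma_m_sq": 0.0,      "sigma_gm_sq": 0.0},
    "S3_M":        {"gamma_expr": 0.0,      "sigma_g_sq": 0.0,      "sigma_m_sq": 0.883333, "sigma_gm_sq": 0.0},
    "S4_GM":       {"gamma_expr": 0.0,      "sigma_g_sq": 0.0,      "sigma_m_sq": 0.0,      "sigma_gm_sq": 0.883333},
    "S5_G_plus_M": {"gamma_expr": 0.0,      "sigma_g_sq": 0.441667, "sigma_m_sq": 0.441667, "sigma_gm_sq": 0.0},
    "S6_E_plus_G": {"gamma_expr": 2.302173, "sigma_g_sq": 0.441667, "sigma_m_sq": 0.0,      "sigma_gm_sq": 0.0},
    "S7_E_plus_M": {"gamma_expr": 2.302173, "sigma_g_sq": 0.0,      "sigma_m_sq": 0.441667, "sigma_gm_sq": 0.0}
  }
}
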