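{
  "center": {
    "C": 20.0,
    "g_NaP": 5.0,
    "g_L": 2.8,
    "E_Na": 50.0,
    "V_mNaP": -40.0,
    "k_mNaP": -6.0,
    "V_hNaP": -55.0,
    "k_hNaP": 10.0,
    "V_tauNaP": -40.0,
    "k_tauNaP": -12.0,
    "tau_hNaP_max": 4000.0,
    "V_min": -50.0,
    "V_max": 0.0
  },
  "network": {
    "E_LF0": -63.0,
    "E_LE0": -50.0,
    "beta_E": 0.1,
    "g_SynE": 0.1,
    "g_SynI": 0.6,
    "E_SynE": -10.0,
    "E_SynI": -75.0,
    "a_30": 0.5,
    "a_V0": 0.5,
    "a_D": 0.35,
    "b_1": 10.0,
    "b_2": 0.1,
    "beta_a": 3.0,
    "include_V0D": true,
    "include_V0V": true,
    "include_V3": true
  }
}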