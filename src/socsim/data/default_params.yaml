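# socsim default parameters, version 1
# Cell electrophysiology (parameter-table values) and the calibrated
# synthetic-periphery constants.  Any override of these values through a
# user config file is logged at INFO level.
version: 1
sbc:
  c_m_pf: 12.0
  e_rest_mv: -65.0
  g_l_ns: 37.0
  g_na_ns: 4592.8
  g_kht_ns: 35.1
  g_klt_ns: 367.4
  g_h_ns: 36.7
  e_na_mv: 50.0
  e_k_mv: -77.0
  e_h_mv: -43.0
  a_syn_ns: 13.0
  syn_decay_ms: 0.2
  e_ex_mv: 0.0
gbc:
  c_m_pf: 12.0
  e_rest_mv: -65.0
  g_l_ns: 37.0
  g_na_ns: 4592.8
  g_kht_ns: 35.1
  g_klt_ns: 367.4
  g_h_ns: 36.7
  e_na_mv: 50.0
  e_k_mv: -77.0
  e_h_mv: -43.0
  a_syn_ns: 4.76
  syn_decay_ms: 0.2
  e_ex_mv: 0.0
mso:
  c_m_pf: 70.0
  e_rest_mv: -55.8
  g_l_ns: 13.0
  g_na_ns: 3900.0
  g_klt_ns: 650.0
  g_h_ns: 520.0
  e_na_mv: 56.2
  e_k_mv: -90.0
  e_h_mv: -35.0
  a_exc_ns: 54.37
  a_inh_ns: 5.5
  e_ex_mv: 0.0
  e_in_mv: -70.0
  tau_exc_ms: 0.17
  tau_inh_rise_ms: 0.14
  tau_inh_decay_ms: 1.6
  delay_exc_ipsi_ms: 1.5
  delay_exc_contra_ms: 1.6
  delay_inh_ipsi_ms: 1.5
  delay_inh_contra_ms: 1.0
periphery:
  threshold_db: {LT: 15.0, MT: 30.0, HT: 75.5}
  slope_db: 6.0
  max_driven_rate_hz: 6000.0
  spontaneous_rate_hz: 30.0
  phase_locking_exponent: 8.0
  latency_intercept_ms: 0.5
  latency_slope_ms_per_um: 0.08
  jitter_intercept_ms: 0.05
  jitter_slope_ms_per_um: 0.04
  firing_prob_intercept: 0.95
  firing_prob_slope_per_um: 0.08
  refractory_ms: 0.7
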