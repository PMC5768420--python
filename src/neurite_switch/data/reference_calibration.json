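{
 "description": "Reference calibration of the substrate-stiffness bistable switch. One parameter set used by every experiment; committed output of experiments.calibrate_to_targets.",
 "model_parameters": {
  "P_T": 10.0,
  "S_E_per_ME": 0.5,
  "S_A_per_MA": 1.0,
  "K_E": 1.4,
  "K_A": 1.0,
  "kappa": 2.0,
  "alpha_E": 2.8,
  "beta_E": 2.0,
  "K_fb": 4.0,
  "n_fb": 6.0,
  "delta_E": 0.5,
  "alpha_A": 20.4,
  "K_i": 5.2,
  "p_i": 4.0,
  "delta_A": 1.0,
  "E_half": 5.0,
  "h_E": 2.0,
  "g_rac": 1.0,
  "R0": 0.1,
  "theta_seg": 4.0,
  "p_neur_SL": 0.98,
  "p_neur_BL": 0.15,
  "cv_cell": 0.2,
  "sigma_dyn": 0.0
 },
 "conditions": [
  {"label": "0.1 kPa", "E_kPa": 0.1},
  {"label": "1 kPa", "E_kPa": 1.0},
  {"label": "20 kPa", "E_kPa": 20.0},
  {"label": "glass", "E_kPa": 1000.0}
 ],
 "uptake": {
  "soft": {"condition_label": "0.1 kPa", "F_max": 1.3333333333333333, "t_half_min": 16.8},
  "stiff": {"condition_label": "20 kPa", "F_max": 1.0, "t_half_min": 24.8}
 },
 "qd": {
  "scale_q_dots_per_flux_hr": 0.18057408523969157,
  "window_hr": 5.0
 },
 "morphometrics": {
  "radius_um": 8.0,
  "n_angles": 360,
  "threshold_over_background": 2.0,
  "min_arc_samples": 2
 },
 "ensemble": {
  "n_cells": 150,
  "t_end_hr": 16.0,
  "t_pheno_hr": 5.0,
  "seed": 2024
 },
 "perturbations": ["none", "paxillin_kd", "cip4_kd", "dynamin_inhibition", "rac1_inhibition", "pxn_delta_LIM34", "pxn_delta_LD1", "pxn_LD13"]
}
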