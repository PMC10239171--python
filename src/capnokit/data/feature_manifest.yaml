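# Capnogram feature manifest (single source of truth for feature naming).
#
# 39 per-breath scalars are aggregated per capnogram as median + SD across
# valid breaths; the SD of plateau_central_time_frac is omitted (it is
# already normalised within each breath), giving 39 + 38 = 77 per-breath
# aggregates. With the 5 whole-capnogram features the vector has 82 entries.
#
# Each feature is assigned to exactly one waveform region for the
# weighted-importance map: phase1 (inspiratory baseline), phase2
# (expiratory upstroke), phase3 (expiratory plateau), phase4a (inspiratory
# downstroke), phase4b (inspiratory baseline) or whole_capnogram.
version: 1
sd_omitted:
  - plateau_central_time_frac
per_breath:
  alpha_deg: phase2
  beta_deg: phase3
  gamma_deg: phase4b
  delta_deg: phase2
  phase2_slope: phase2
  phase3_slope: phase3
  phase4a_slope: phase4a
  phase2_fit_rmse: phase2
  phase3_fit_rmse: phase3
  phase4a_fit_rmse: phase4a
  phase3_quad_coeff: phase3
  phase3_concavity: phase3
  baseline_pco2: phase1
  plateau_mean: phase3
  etco2: phase3
  pco2_range: whole_capnogram
  plateau_central_time_frac: phase3
  breath_duration: whole_capnogram
  exp_duration: whole_capnogram
  insp_duration: whole_capnogram
  phase2_duration: phase2
  phase3_duration: phase3
  phase4a_duration: phase4a
  ei_ratio: whole_capnogram
  rise_time_25_75: phase2
  fall_time_75_25: phase4a
  time_to_peak_frac: whole_capnogram
  phase2_frac_of_exp: phase2
  phase3_frac_of_exp: phase3
  auc_total: whole_capnogram
  auc_phase2: phase2
  auc_phase3: phase3
  auc_per_second: whole_capnogram
  max_upslope: phase2
  min_downslope: phase4a
  phase2_curvature: phase2
  alpha_beta_ratio: whole_capnogram
  plateau_slope_over_height: phase3
  within_breath_pco2_sd: whole_capnogram
whole_capnogram:
  respiratory_rate: whole_capnogram
  max_etco2: whole_capnogram
  etco2_short_term_variability: whole_capnogram
  pco2_absolute_variability: whole_capnogram
  valid_breath_fraction: whole_capnogram
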