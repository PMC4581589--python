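arm_fraction_lcm: 0.5
baseline_sqrt_cd4_mean: 14.18
baseline_sqrt_cd4_sd: 3.41
cd4_drift_failing: -0.12
cd4_drift_secondline: 0.25
cd4_obs_noise_sd: 0.8
cd4_process_noise_sd: 0.35
cd4_responder_gain: 4.0
cd4_reversion: 0.05
death_cd4_slope: 0.02
death_intercept: -4.3
death_secondline: -0.25
death_who4_recent: 1.5
event_hazards:
  esoph_candida:
  - -5.5
  - 0.008
  tb_extra:
  - -6.0
  - 0.008
  tb_pulm:
  - -5.0
  - 0.006
  who3:
  - -3.8
  - 0.008
  who4:
  - -4.6
  - 0.01
failure_logit_intercept: 1.6
failure_logit_slope: 0.18
lcm_action_threshold: 100.0
ltfu_hazard: 0.001
n_individuals: 200
n_intervals: 30
p_bmi_low_baseline: 0.15
p_cotrim_start: 0.03
p_cotrim_stop: 0.08
p_cotrimoxazole: 0.5
p_flag_onset: 0.005
p_flag_onset_lowcd4: 0.02
p_flag_recover: 0.05
p_hb_low_baseline: 0.05
p_missed_doses: 0.05
p_missed_visits: 0.01
p_who4_weeks24to48: 0.08
seed: 20240
substudy_entry_interval: 1
substudy_fraction: 0.27
switch_base: 0.0008
switch_lcm_low_cd4: 0.055
switch_who3_recur_cdm: 0.06
switch_who4_cdm: 0.22
switch_who4_lcm: 0.18
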