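table,row,printed_F,g1_n,g1_mean,g1_sd,g2_n,g2_mean,g2_sd,g3_n,g3_mean,g3_sd
demographics,age_years,0.101,45,37.69,12.26,50,37.36,12.28,50,36.64,10.63
demographics,mean_arterial_pressure_mmHg,0.689,45,88.78,7.24,50,88.10,5.32,50,87.10,8.23
demographics,end_tidal_co2_mmHg,1.064,45,40.82,4.64,50,40.34,3.17,50,39.50,5.38
tfa,phase_overall_deg,6.727,45,46.25,13.02,50,54.19,8.95,50,54.46,14.28
tfa,phase_left_deg,4.084,45,47.45,13.49,50,54.36,9.85,50,54.26,16.03
tfa,phase_right_deg,8.117,45,45.05,14.10,50,54.02,9.50,50,54.67,14.54
tfa,gain_overall_pct_per_mmHg,2.847,45,1.15,0.36,50,1.09,0.30,50,1.23,0.24
tfa,gain_left_pct_per_mmHg,2.762,45,1.13,0.34,50,1.07,0.29,50,1.21,0.26
tfa,gain_right_pct_per_mmHg,2.463,45,1.16,0.40,50,1.10,0.31,50,1.25,0.27
hrv,nn_intervals_ms,1.053,43,864.89,106.38,49,832.28,140.07,49,834.32,106.46
hrv,sdnn_log_ms,1.326,43,1.58,0.18,49,1.55,0.18,49,1.61,0.15
hrv,rmssd_log_ms,1.007,43,1.52,0.23,49,1.48,0.22,49,1.54,0.18
hrv,tp_log_ms2,1.331,43,3.06,0.39,49,3.02,0.39,49,3.14,0.30
hrv,vlf_log_ms2,0.475,43,2.66,0.40,49,2.59,0.44,49,2.66,0.31
hrv,lf_log_ms2,1.788,43,2.34,0.44,49,2.40,0.39,49,2.50,0.36
hrv,hf_log_ms2,2.442,43,2.55,0.49,49,2.48,0.49,49,2.68,0.40
hrv,lf_nu,1.786,43,39.71,15.58,49,45.45,16.18,49,40.66,15.70
hrv,hf_nu,1.786,43,60.29,15.58,49,54.55,16.18,49,59.34,15.70
hrv,lf_hf_ratio,2.318,43,0.93,0.12,49,0.99,0.19,49,0.94,0.11
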