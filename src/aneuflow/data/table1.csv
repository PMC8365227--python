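device,mcr_pct,el_w_m3,el_reduction_pct,avg_velocity_m_s,vel_reduction_pct,inflow_rate_mm3_s,inflow_reduction_pct
Control,0.0,66.09,0.00,0.0114,0.00,224.4,0.00
Enterprise (single),7.0,58.01,12.23,0.01,12.28,196.4,12.33
Enterprise (double),13.0,46.7,29.34,0.00543,52.37,119.0,47.36
Enterprise (triple),18.0,36.05,45.45,0.00415,63.60,48.5,78.43
LVIS (single),20.4,34.38,47.98,0.00339,70.26,54.0,75.89
LVIS (double),36.3,20.49,69.00,0.00241,78.86,26.5,88.24
LVIS compaction (single),35.4,22.21,66.39,0.00254,77.72,20.1,91.15
LVIS compaction (double),63.9,6.72,89.83,0.00156,86.32,15.9,92.93
Pipeline,26.8,30.68,53.58,0.00241,78.86,24.9,88.82
Pipeline compaction,47.8,12.9,80.48,0.0019,83.33,15.7,92.90
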