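# Calibrated parameter set, Jubilaeumswarte beech stand (Vienna Woods, calcareous Flysch)
f_occult = 15395.36
f_dry = 0.00
theta0_mineral = 0.01
theta1_mineral = 0.25
theta2_mineral = 0.33
theta3_mineral = 0.39
theta0_immobil = 0.04
theta1_immobil = 0.18
theta2_immobil = 0.29
theta3_immobil = 0.38
hl_stable_yr = 67.34
hl_labile_d = 13.00
k_m_immobil = 1.05
v_coeff_immobil = 2.11
f_q10_immobil = 2.77
f_q10_mineral = 2.22
v_starve_plant = 0.07
v_sat_plant = 0.00
k_m_plant = 0.95
acu_starve = 913.76
acu_sat = 2166.95
f_labile = 0.07
f_fol = 0.82
hl_ads_d = 71.10
k_l_ads = 11.68
k_max_ads = 7057.02
z_r = 500.0
sulfatase_enabled = false
init_labile = 6804.58
init_stable = 61845.05
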