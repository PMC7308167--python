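# Calibrated parameter set, Exelberg beech stand (Vienna Woods, Flysch bedrock)
f_occult = 33922.35
f_dry = 0.00
theta0_mineral = 0.07
theta1_mineral = 0.13
theta2_mineral = 0.23
theta3_mineral = 0.36
theta0_immobil = 0.04
theta1_immobil = 0.07
theta2_immobil = 0.16
theta3_immobil = 0.33
hl_stable_yr = 54.71
hl_labile_d = 21.99
k_m_immobil = 1.81
v_coeff_immobil = 2.11
f_q10_immobil = 2.37
f_q10_mineral = 2.19
v_starve_plant = 0.11
v_sat_plant = 0.00
k_m_plant = 1.16
acu_starve = 1141.79
acu_sat = 1367.79
f_labile = 0.18
f_fol = 0.74
hl_ads_d = 205.00
k_l_ads = 12.53
k_max_ads = 6085.48
z_r = 500.0
sulfatase_enabled = false
init_labile = 5054.55
init_stable = 51175.13
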