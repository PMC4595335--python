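soil,depth_bottom_mm,bulk_density_g_cm3,awc,ksat_mm_h,clay_pct,silt_pct,sand_pct
Grey desert soil,300,1.59,0.14,33.41,6.43,19.78,73.80
Grey desert soil,600,1.40,0.17,32.00,11.94,40.31,47.75
Irrigated desert soil,200,1.52,0.17,12.64,16.05,46.48,37.47
Irrigated desert soil,400,1.40,0.12,11.94,21.97,48.28,29.75
Irrigated desert soil,600,1.46,0.07,8.13,25.71,68.03,6.26
Irrigated desert soil,800,1.51,0.09,11.43,19.24,69.54,11.22
Irrigated desert soil,1000,1.53,0.07,8.38,26.74,62.17,11.08
Aeolian sandy soil,500,1.40,0.05,151.38,1.14,5.71,93.14
Aeolian sandy soil,1000,1.40,0.05,120.65,3.10,13.99,82.91
Sierozem,210,1.20,0.14,2.18,21.00,36.00,43.00
Sierozem,450,1.20,0.14,3.73,14.00,43.00,43.00
Sierozem,1070,1.40,0.14,3.57,16.00,51.00,33.00
Sierozem,1500,1.40,0.22,3.26,12.00,75.00,33.00
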