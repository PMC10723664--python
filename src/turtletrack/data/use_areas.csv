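ptt,area_label,kind,depth_m,size_km2
108507,a,foraging_f,2.4,0.034
108508,a,foraging_f,2.9,0.108
120325,a,foraging_f,1.3,0.023
120326,a,foraging_f,2.9,0.033
132092,a,foraging_f,1.6,0.014
132093,a,foraging_f,2.4,0.032
140712,a,foraging_f,3.0,0.198
140713,a,foraging_f,1.7,0.053
151800,a,foraging_f,3.4,0.145
151801,a,foraging_f,6.8,0.007
163691,a,foraging_f,3.0,0.022
163691,b,foraging_f,8.4,0.003
163692,a,foraging_f,3.0,0.055
163693,a,foraging_f,2.1,0.022
163693,b,foraging_f,2.7,0.080
172208,a,foraging_f,3.0,0.088
172209,a,foraging_f,3.0,0.018
172209,b,foraging_f,8.4,0.049
174108,a,foraging_f,3.0,0.034
108507,a,rest_day_r,9.8,0.017
108508,a,rest_day_r,9.3,0.004
120325,a,rest_day_r,6.7,0.005
132092,a,rest_day_r,7.6,0.060
132093,a,rest_day_r,5.3,0.011
140712,a,rest_day_r,7.8,0.018
140713,a,rest_day_r,9.5,0.019
108508,a,rest_night_r,9.7,0.0025
120325,a,rest_night_r,6.6,0.0095
120326,a,rest_night_r,1.6,0.0046
132092,a,rest_night_r,3.5,0.0560
132093,a,rest_night_r,4.8,0.0119
140712,a,rest_night_r,10.7,0.0101
140712,b,rest_night_r,11.5,0.0033
163692,a,rest_night_r,9.2,0.0039
172209,a,rest_night_r,10.3,0.003
174108,a,rest_night_r,10.7,0.006
120325,a,cool_refuge_c,10.0,0.487
140712,a,cool_refuge_c,9.6,0.667
140712,b,cool_refuge_c,12.4,0.527
163692,a,cool_refuge_c,10.1,0.042
172208,a,cool_refuge_c,10.5,0.014
174108,a,cool_refuge_c,9.9,0.005
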