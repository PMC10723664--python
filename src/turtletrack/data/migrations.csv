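ptt,deploy_site,deploy_date,departure_date,end_date,final_location,sex,scl_min_cm,pre_departure_foray,path_km,bearing_deg,bearing_sd_deg,straightness,straightness_sd,rate_kmh,rate_sd_kmh,current_ms,current_sd_ms,n_fixes
140712,Somerset Long Bay,2014-08-08,2015-06-02,2015-06-09,open ocean,U,66.8,Y,386,241.8,0.46,0.93,0.24,2.53,0.79,0.58,0.38,41
140713,Wreck Hill,2014-08-11,2015-08-31,2015-10-27,Bimini Bahamas,M,63.9,N,2025,254.2,0.59,0.96,0.08,2.20,0.69,1.35,0.73,40
151801,Wreck Hill,2015-08-17,2015-09-08,2015-09-24,open ocean,U,66.6,Y,800,210.1,0.60,0.90,0.28,2.25,0.70,0.79,0.33,76
163691,Somerset Long Bay,2016-08-10,2016-08-27,2016-09-29,Andros Bahamas,F,67.1,Y,1653,232.5,0.60,0.92,0.24,2.07,0.71,0.83,0.33,390
11674,Outside Daniels Head,1998-08-08,1998-08-23,1998-09-29,Baracoa Cuba,F,78.6,U,2043,218.0,0.85,0.92,0.23,2.28,0.98,0.83,0.36,34
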