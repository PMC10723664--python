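ptt,scl_min_cm,site,deploy_date,days_deployed,data_days,n_fixes,ud25_km2,ud50_km2,ud90_km2,mcp_km2,post_migration,departed
108507,60.6,Blue Hole,2011-08-03,359,194,478,0.01,0.03,0.19,1.19,False,False
108508,48.4,Vixen,2011-08-11,315,180,207,0.08,0.20,0.71,1.20,False,False
120325,59.7,Wreck Hill,2012-08-10,289,217,490,0.03,0.08,0.39,1.13,False,False
120326,66.2,Annies Bay,2012-08-14,37,38,181,0.01,0.03,0.11,0.29,False,False
132092,69.4,Baileys Bay,2013-08-07,96,97,501,0.03,0.09,0.42,2.24,False,False
132093,68.0,Annies Bay,2013-08-13,66,67,252,0.29,0.68,2.39,5.39,False,False
140712,66.8,Somerset Long Bay,2014-08-08,779,304,1641,0.06,0.17,0.90,2.62,False,True
140713,63.9,Wreck Hill,2014-08-11,504,485,306,0.10,0.25,0.92,0.52,False,True
140713,63.9,Wreck Hill,2014-08-11,,,,0.37,0.96,4.45,2.42,True,True
151800,61.0,Ft. St. Catherine,2015-08-14,58,59,303,0.13,0.41,2.29,2.73,False,False
151801,66.6,Wreck Hill,2015-08-17,117,41,355,0.23,0.63,2.55,0.44,False,True
163691,67.1,Somerset Long Bay,2016-08-10,50,51,591,0.18,0.58,3.05,2.81,False,True
163692,58.5,Somerset Long Bay,2016-08-15,329,321,2007,0.02,0.08,0.43,1.00,False,False
163693,57.2,Long Bay,2016-08-18,616,591,500,0.09,0.24,1.54,16.98,False,False
172208,59.0,Somerset Long Bay,2017-08-18,327,318,488,0.72,1.96,8.33,24.50,False,False
172209,65.7,King Charles Hole,2018-08-16,309,281,515,0.97,2.40,9.01,45.75,False,False
174108,59.2,Methelin Bay,2018-08-20,291,281,174,0.04,0.11,0.41,2.52,False,False
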