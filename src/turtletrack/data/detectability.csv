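ptt,first_capture,last_observation,residency_months,single_site,n_sets,n_captures
108507,2003-08-04,2012-07-27,108,True,8,4
108508,2004-08-12,2012-06-21,93,True,16,3
120325,2012-07-30,2014-08-11,144,True,26,4
120326,2010-08-13,2012-09-20,109,True,11,4
132092,2002-08-07,2013-11-11,135,True,31,6
132093,2003-12-01,2014-08-15,140,True,10,2
140712,2014-08-08,2016-09-25,25,True,5,1
140713,2001-08-08,2015-12-28,173,True,32,2
151800,2015-08-14,2015-10-11,2,True,,
151801,2015-08-17,2015-12-12,4,True,,
163691,2013-08-14,2016-12-29,40,True,8,2
163692,2015-08-19,2017-07-10,23,True,3,2
163693,2006-07-28,2018-04-27,141,True,11,7
172208,2017-08-18,2018-07-11,11,True,,
172209,2004-04-27,2019-06-05,181,False,,
174108,2013-08-14,2019-06-05,70,False,,4
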