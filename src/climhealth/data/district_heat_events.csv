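start,end,counties,near_threshold_note
2000-08-28,2000-08-30,Union;Webster,
2002-08-02,2002-08-04,Union,
2002-09-07,2002-09-10,Henderson;Union;Webster,
2005-07-24,2005-07-26,Union,
2005-08-09,2005-08-14,Henderson;McLean;Union;Webster,
2006-07-18,2006-07-21,Union,
2006-07-30,2006-08-03,Union;Webster,
2006-08-06,2006-08-10,Union,
2007-07-31,2007-08-24,Daviess;Hancock;Henderson;McLean;Ohio;Union;Webster,
2007-08-27,2007-08-29,Henderson;McLean;Union;Webster,all_others_two_days
2007-09-02,2007-09-05,Daviess;Henderson;McLean;Union;Webster,all_others_two_days
2010-07-23,2010-07-25,Hancock,all_others_two_days
2010-08-01,2010-08-04,Daviess;Hancock;Henderson;McLean;Ohio;Union;Webster,
2010-08-08,2010-08-15,Daviess;Hancock;Henderson;McLean;Ohio;Union;Webster,
2010-08-19,2010-08-22,Daviess;Hancock;Henderson;McLean;Ohio;Union;Webster,
2010-08-31,2010-09-02,Daviess;Hancock;Henderson;McLean;Ohio;Union;Webster,
2010-09-19,2010-09-23,Daviess;Hancock;Henderson;McLean;Ohio;Union;Webster,
2011-08-31,2011-09-03,Daviess;Hancock;Henderson;McLean;Ohio;Union;Webster,
2012-06-18,2012-06-21,Henderson;McLean;Union;Webster,
2012-06-23,2012-06-25,Henderson;McLean;Webster,
2012-06-27,2012-07-10,Daviess;Hancock;Henderson;McLean;Ohio;Union;Webster,
2012-07-15,2012-08-09,Daviess;Hancock;Henderson;McLean;Ohio;Union;Webster,
2012-08-23,2012-08-25,Daviess;Henderson;McLean;Union;Webster,all_others_two_days
2012-08-28,2012-08-31,Daviess;Hancock;Henderson;McLean;Ohio;Union;Webster,hancock_one_degree_shy
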