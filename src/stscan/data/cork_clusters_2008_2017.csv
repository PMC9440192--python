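cluster,start_date,end_date,duration_days,expected,observed,p_value,test_statistic
1,2011/09/15,2011/09/15,0,0.010,2,0.111,8.551
2,2015/10/27,2015/11/2,6,0.010,2,0.498,8.551
3,2009/08/04,2009/08/05,1,0.015,2,0.852,7.745
4,2008/12/27,2009/01/01,5,0.015,2,0.852,7.745
5,2011/09/28,2011/10/10,12,0.103,3,0.854,7.226
6,2010/11/14,2010/12/11,27,0.021,2,0.934,7.175
7,2009/11/10,2009/11/23,12,0.023,2,0.956,6.942
8,2014/02/20,2014/02/25,5,0.023,2,0.956,6.942
9,2015/09/03,2015/09/05,2,0.026,2,0.978,6.733
10,2011/11/09,2011/11/11,2,0.026,2,0.978,6.733
11,2011/07/26,2011/08/11,16,0.039,2,0.998,5.936
12,2008/09/25,2008/10/22,27,0.046,2,0.998,5.579
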