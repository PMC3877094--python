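probeset_id,n_pairs,pct_present_a,pct_present_b,pct_increase,pct_decrease,mean_log2fc,linear_fc,t_p,bonf_p,max_signal,category,passed_present_gate
CMN0002_s1_at,9,1.0000,1.0000,1.0000,0.0000,6.5058,90.8732,9.9669e-14,3.0897e-12,11.8475,increased_homogeneous,True
CMN0001_s1_at,9,1.0000,1.0000,1.0000,0.0000,5.6668,50.8014,1.2506e-12,3.8769e-11,10.8687,increased_homogeneous,True
CMN0005_s1_at,9,1.0000,1.0000,1.0000,0.0000,4.9403,30.7031,5.2569e-12,1.6296e-10,11.9916,increased_homogeneous,True
CMN0003_s1_at,9,1.0000,1.0000,1.0000,0.0000,4.8216,28.2778,8.5448e-12,2.6489e-10,12.6322,increased_homogeneous,True
CMN0006_s1_at,9,1.0000,1.0000,1.0000,0.0000,4.5237,23.0016,1.1772e-12,3.6494e-11,9.9717,increased_homogeneous,True
DSP0003_s1_at,9,1.0000,1.0000,1.0000,0.0000,3.5179,11.4551,4.6163e-10,1.4310e-08,9.0290,increased_homogeneous,True
NDE0002_s1_at,9,1.0000,1.0000,1.0000,0.0000,2.6389,6.2288,4.6896e-09,1.4538e-07,8.2887,increased_homogeneous,True
DSP0005_s1_at,9,1.0000,1.0000,1.0000,0.0000,2.3790,5.2018,8.5971e-12,2.6651e-10,9.2635,increased_homogeneous,True
CMN0004_s1_at,9,1.0000,1.0000,1.0000,0.0000,2.2501,4.7570,2.2597e-12,7.0051e-11,9.0945,increased_homogeneous,True
DSP0001_s1_at,9,1.0000,1.0000,1.0000,0.0000,2.1305,4.3788,6.6087e-13,2.0487e-11,6.9237,increased_homogeneous,True
DSP0004_s1_at,9,1.0000,1.0000,1.0000,0.0000,1.4960,2.8206,1.5176e-10,4.7045e-09,8.8930,increased_homogeneous,True
DSP0002_s1_at,9,1.0000,1.0000,1.0000,0.0000,1.3802,2.6030,4.2838e-07,1.3280e-05,8.5393,increased_homogeneous,True
DSP0002_s2_at,9,1.0000,1.0000,1.0000,0.0000,1.3145,2.4871,1.1048e-08,3.4248e-07,8.7211,increased_homogeneous,True
NDE0003_s1_at,9,1.0000,1.0000,1.0000,0.0000,1.2561,2.3884,2.2854e-09,7.0848e-08,8.1368,increased_homogeneous,True
NDE0001_s1_at,9,1.0000,1.0000,0.6667,0.0000,0.9507,1.9328,7.7593e-07,2.4054e-05,6.1076,increased_homogeneous,True
ISP0001_s1_at,9,1.0000,1.0000,0.0000,0.0000,0.2740,1.2091,3.4478e-04,1.0688e-02,6.8739,not_significant,True
NUL0011_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.2475,-1.1871,4.6141e-03,1.4304e-01,6.5237,not_significant,True
NUL0002_s1_at,9,1.0000,1.0000,0.0000,0.1111,-0.2110,-1.1575,6.1357e-02,1.0000e+00,6.5296,not_significant,True
NUL0004_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.2035,-1.1515,2.1285e-02,6.5984e-01,6.9388,not_significant,True
ISP0002_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.2002,-1.1488,7.8649e-03,2.4381e-01,5.8631,not_significant,True
NUL0012_s1_at,9,1.0000,1.0000,0.0000,0.0000,0.1749,1.1289,1.4265e-02,4.4220e-01,9.2563,not_significant,True
NUL0008_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.1182,-1.0854,1.5530e-01,1.0000e+00,4.5478,not_significant,True
NUL0003_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0994,-1.0714,1.4550e-01,1.0000e+00,7.0992,not_significant,True
NUL0002_s2_at,9,1.0000,1.0000,0.0000,0.0000,-0.0935,-1.0669,2.6271e-02,8.1440e-01,6.2504,not_significant,True
NUL0010_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0880,-1.0629,2.9862e-01,1.0000e+00,7.4567,not_significant,True
NUL0006_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0858,-1.0612,1.3635e-01,1.0000e+00,8.0625,not_significant,True
NUL0007_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0784,-1.0559,3.2397e-01,1.0000e+00,7.4708,not_significant,True
NUL0009_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0634,-1.0449,2.0835e-01,1.0000e+00,3.7940,not_significant,True
NUL0001_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0548,-1.0387,4.0633e-01,1.0000e+00,5.8933,not_significant,True
NUL0011_s2_at,9,1.0000,1.0000,0.0000,0.0000,0.0512,1.0361,5.2169e-01,1.0000e+00,6.7524,not_significant,True
NUL0005_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0158,-1.0110,8.3051e-01,1.0000e+00,6.2053,not_significant,True
ABS0001_s1_at,9,0.0000,0.0000,0.0000,0.0000,0.0000,1.0000,1.0000e+00,1.0000e+00,0.0000,not_significant,False
ABS0002_s1_at,9,0.0000,0.0000,0.0000,0.0000,0.0000,1.0000,1.0000e+00,1.0000e+00,0.0000,not_significant,False
ABS0003_s1_at,9,0.0000,0.0000,0.0000,0.0000,0.0000,1.0000,1.0000e+00,1.0000e+00,0.0000,not_significant,False
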