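probeset_id,n_pairs,pct_present_a,pct_present_b,pct_increase,pct_decrease,mean_log2fc,linear_fc,t_p,bonf_p,max_signal,category,passed_present_gate
CMN0002_s1_at,9,1.0000,1.0000,1.0000,0.0000,4.5898,24.0805,7.9617e-12,2.4681e-10,9.9063,increased_homogeneous,True
CMN0001_s1_at,9,1.0000,1.0000,1.0000,0.0000,4.1297,17.5047,7.8162e-16,2.4230e-14,9.4231,increased_homogeneous,True
CMN0005_s1_at,9,1.0000,1.0000,1.0000,0.0000,3.5949,12.0832,3.8446e-11,1.1918e-09,10.6561,increased_homogeneous,True
CMN0003_s1_at,9,1.0000,1.0000,1.0000,0.0000,3.5100,11.3921,4.7253e-13,1.4648e-11,11.3549,increased_homogeneous,True
CMN0006_s1_at,9,1.0000,1.0000,1.0000,0.0000,3.1666,8.9793,1.9113e-13,5.9249e-12,8.5934,increased_homogeneous,True
ISP0001_s1_at,9,1.0000,1.0000,1.0000,0.0000,2.8042,6.9849,1.1591e-12,3.5931e-11,9.3526,increased_homogeneous,True
ISP0002_s1_at,9,1.0000,1.0000,1.0000,0.0000,2.6247,6.1676,1.7240e-11,5.3443e-10,8.5257,increased_homogeneous,True
CMN0004_s1_at,9,1.0000,1.0000,1.0000,0.0000,1.7958,3.4721,2.4234e-10,7.5124e-09,8.4737,increased_homogeneous,True
NUL0011_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.1527,-1.1117,3.9122e-03,1.2128e-01,6.5237,not_significant,True
NDE0002_s1_at,9,1.0000,1.0000,0.0000,0.0000,0.1445,1.1054,3.1215e-02,9.6765e-01,5.9211,not_significant,True
NUL0001_s1_at,9,1.0000,1.0000,0.0000,0.0000,0.1324,1.0961,4.0800e-02,1.0000e+00,5.8838,not_significant,True
NUL0005_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.1313,-1.0953,2.0660e-01,1.0000e+00,6.2053,not_significant,True
DSP0003_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.1275,-1.0924,7.7160e-02,1.0000e+00,5.4422,not_significant,True
NUL0012_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.1213,-1.0877,1.6767e-01,1.0000e+00,8.9481,not_significant,True
NUL0008_s1_at,9,1.0000,1.0000,0.0000,0.0000,0.1192,1.0861,1.6949e-02,5.2541e-01,4.5478,not_significant,True
NUL0011_s2_at,9,1.0000,1.0000,0.0000,0.0000,-0.0812,-1.0579,3.6287e-01,1.0000e+00,6.7524,not_significant,True
NUL0002_s2_at,9,1.0000,1.0000,0.0000,0.0000,-0.0800,-1.0570,1.9002e-01,1.0000e+00,6.2504,not_significant,True
NDE0003_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0709,-1.0503,7.0532e-03,2.1865e-01,6.9765,not_significant,True
NUL0009_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0563,-1.0398,2.0276e-01,1.0000e+00,3.7940,not_significant,True
NUL0010_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0439,-1.0309,5.3754e-01,1.0000e+00,7.4567,not_significant,True
NUL0003_s1_at,9,1.0000,1.0000,0.0000,0.0000,0.0323,1.0227,5.6034e-01,1.0000e+00,7.0992,not_significant,True
DSP0005_s1_at,9,1.0000,1.0000,0.0000,0.0000,0.0311,1.0218,7.0762e-01,1.0000e+00,6.9140,not_significant,True
DSP0002_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0280,-1.0196,7.1465e-01,1.0000e+00,7.2762,not_significant,True
DSP0002_s2_at,9,1.0000,1.0000,0.0000,0.0000,0.0277,1.0194,7.1992e-01,1.0000e+00,7.4632,not_significant,True
NUL0002_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0223,-1.0155,8.1159e-01,1.0000e+00,6.6721,not_significant,True
DSP0001_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0188,-1.0131,8.0827e-01,1.0000e+00,4.7946,not_significant,True
NUL0006_s1_at,9,1.0000,1.0000,0.0000,0.0000,0.0181,1.0126,7.3888e-01,1.0000e+00,8.1805,not_significant,True
NDE0001_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0133,-1.0092,8.9129e-01,1.0000e+00,5.1270,not_significant,True
NUL0004_s1_at,9,1.0000,1.0000,0.0000,0.0000,0.0122,1.0085,7.9142e-01,1.0000e+00,6.9388,not_significant,True
DSP0004_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0082,-1.0057,8.7696e-01,1.0000e+00,7.4519,not_significant,True
NUL0007_s1_at,9,1.0000,1.0000,0.0000,0.0000,-0.0072,-1.0050,9.4366e-01,1.0000e+00,7.6488,not_significant,True
ABS0001_s1_at,9,0.0000,0.0000,0.0000,0.0000,0.0000,1.0000,1.0000e+00,1.0000e+00,0.0000,not_significant,False
ABS0002_s1_at,9,0.0000,0.0000,0.0000,0.0000,0.0000,1.0000,1.0000e+00,1.0000e+00,0.0000,not_significant,False
ABS0003_s1_at,9,0.0000,0.0000,0.0000,0.0000,0.0000,1.0000,1.0000e+00,1.0000e+00,0.0000,not_significant,False
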