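probeset_id	BL_01.signal	BL_01.detection	BL_02.signal	BL_02.detection	BL_03.signal	BL_03.detection	D7_01.signal	D7_01.detection	D7_02.signal	D7_02.detection	D7_03.signal	D7_03.detection	SLE_01.signal	SLE_01.detection	SLE_02.signal	SLE_02.detection	SLE_03.signal	SLE_03.detection
ABS0001_s1_at	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A
ABS0002_s1_at	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A
ABS0003_s1_at	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A	0.0000	A
CMN0001_s1_at	5.3397	P	5.4817	P	5.1736	P	9.4770	P	9.2622	P	9.5300	P	10.9058	P	10.8046	P	10.8956	P
CMN0002_s1_at	5.5296	P	5.3080	P	5.4324	P	10.0250	P	9.9900	P	9.7038	P	11.7482	P	12.1394	P	11.6549	P
CMN0003_s1_at	7.8922	P	7.9147	P	8.0106	P	11.3394	P	11.4721	P	11.2532	P	12.5675	P	12.7495	P	12.5794	P
CMN0004_s1_at	6.8840	P	6.7142	P	6.7429	P	8.5500	P	8.3959	P	8.4753	P	9.1251	P	9.0021	P	9.1564	P
CMN0005_s1_at	7.3487	P	7.3902	P	6.7708	P	10.8536	P	10.5877	P	10.5271	P	11.9417	P	12.1867	P	11.8463	P
CMN0006_s1_at	5.5464	P	5.2953	P	5.4688	P	8.7481	P	8.5929	P	8.4393	P	9.7908	P	9.9581	P	10.1662	P
DSP0001_s1_at	4.6508	P	4.8392	P	4.8939	P	4.9150	P	4.6037	P	4.6897	P	7.0450	P	6.8827	P	6.8434	P
DSP0002_s1_at	7.3858	P	7.0953	P	7.3476	P	7.4680	P	7.0063	P	7.3071	P	8.6155	P	8.6339	P	8.3686	P
DSP0002_s2_at	7.0796	P	7.6273	P	7.3330	P	7.2489	P	7.5398	P	7.6008	P	8.6408	P	8.6884	P	8.8340	P
DSP0003_s1_at	5.6322	P	5.4590	P	5.2354	P	5.3383	P	5.1913	P	5.2319	P	9.3313	P	9.0543	P	8.7015	P
DSP0004_s1_at	7.3547	P	7.4979	P	7.5031	P	7.6134	P	7.2231	P	7.4746	P	8.8541	P	8.9105	P	8.9144	P
DSP0005_s1_at	6.9221	P	6.5730	P	7.0268	P	7.1248	P	6.7142	P	6.9030	P	9.3970	P	9.2352	P	9.1583	P
ISP0001_s1_at	6.5923	P	6.8175	P	6.5966	P	9.3344	P	9.3330	P	9.3905	P	6.8002	P	7.0410	P	6.7805	P
ISP0002_s1_at	5.9433	P	5.8689	P	5.7772	P	8.6316	P	8.4500	P	8.4955	P	5.5461	P	5.7246	P	5.7249	P
NDE0001_s1_at	4.7922	P	5.1667	P	5.3323	P	5.0982	P	5.1874	P	5.0954	P	5.9734	P	6.2481	P	6.1013	P
NDE0002_s1_at	5.9191	P	5.8240	P	5.6619	P	5.9770	P	6.0056	P	5.7807	P	8.0425	P	8.3483	P	8.4753	P
NDE0003_s1_at	7.0729	P	6.8306	P	7.0259	P	6.9691	P	6.8726	P	6.9162	P	8.0959	P	8.2498	P	8.0647	P
NUL0001_s1_at	5.6755	P	5.8921	P	5.8302	P	5.7082	P	6.2117	P	5.7316	P	5.8495	P	6.0302	P	5.8002	P
NUL0002_s1_at	6.4700	P	6.4603	P	6.6584	P	6.8436	P	6.5889	P	6.5837	P	6.3358	P	6.8490	P	6.3189	P
NUL0002_s2_at	6.2379	P	6.0912	P	6.4220	P	6.2141	P	6.0020	P	6.2007	P	6.3575	P	6.1295	P	5.9838	P
NUL0003_s1_at	7.2200	P	7.1352	P	6.9425	P	7.0197	P	7.0506	P	6.9512	P	6.7634	P	6.9990	P	7.1599	P
NUL0004_s1_at	6.8076	P	7.0099	P	6.9987	P	6.9742	P	6.8593	P	6.7466	P	6.8177	P	6.9467	P	6.5002	P
NUL0005_s1_at	6.3585	P	6.1141	P	6.1433	P	5.9530	P	5.9558	P	6.2334	P	6.2849	P	6.1684	P	5.9850	P
NUL0006_s1_at	8.0584	P	7.9716	P	8.1576	P	8.1676	P	8.0276	P	8.3462	P	7.9274	P	8.1540	P	7.9354	P
NUL0007_s1_at	7.6673	P	7.0686	P	7.6765	P	7.6200	P	7.8900	P	7.4365	P	7.4120	P	7.4745	P	7.4086	P
NUL0008_s1_at	4.7552	P	4.3932	P	4.4950	P	4.4883	P	4.6775	P	4.4692	P	4.2118	P	4.4308	P	4.4652	P
NUL0009_s1_at	3.6857	P	3.7810	P	3.9153	P	3.8209	P	3.7324	P	3.5849	P	3.6552	P	3.9941	P	3.6235	P
NUL0010_s1_at	7.4718	P	7.5196	P	7.3787	P	7.1984	P	7.2966	P	7.6180	P	7.2231	P	7.1308	P	7.2995	P
NUL0011_s1_at	6.3228	P	6.7368	P	6.5115	P	6.3953	P	6.2873	P	6.4942	P	6.4447	P	6.3092	P	6.2605	P
NUL0011_s2_at	6.6060	P	6.7527	P	6.8986	P	6.8261	P	6.2445	P	6.3134	P	6.7560	P	6.5231	P	6.8331	P
NUL0012_s1_at	8.7126	P	9.0207	P	9.1111	P	8.9373	P	8.6297	P	8.8642	P	9.1054	P	9.5145	P	9.1490	P
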