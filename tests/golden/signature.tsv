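probeset_id	gene_symbol	category	fc_disease	fc_immunised	reassigned_flag
CMN0001_s1_at	CMN0001	common	50.8014	17.5047	False
CMN0002_s1_at	CMN0002	common	90.8732	24.0805	False
CMN0003_s1_at	CMN0003	common	28.2778	11.3921	False
CMN0004_s1_at	CMN0004	common	4.7570	3.4721	False
CMN0005_s1_at	CMN0005	common	30.7031	12.0832	False
CMN0006_s1_at	CMN0006	common	23.0016	8.9793	False
DSP0001_s1_at	DSP0001	disease_specific	4.3788	nan	False
DSP0002_s1_at	DSP0002	disease_specific	2.6030	nan	False
DSP0002_s2_at	DSP0002	disease_specific	2.4871	nan	False
DSP0003_s1_at	DSP0003	disease_specific	11.4551	nan	False
DSP0004_s1_at	DSP0004	disease_specific	2.8206	nan	False
DSP0005_s1_at	DSP0005	disease_specific	5.2018	nan	False
ISP0001_s1_at	ISP0001	immunised_specific	nan	6.9849	False
ISP0002_s1_at	ISP0002	immunised_specific	nan	6.1676	False
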