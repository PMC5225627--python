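population	a_r	ssr_he	fis	fis_p	theta_watterson	snp_he	tajimas_d	tajimas_d_p
Aha09	2.7	0.392	0.073	0.051	0.0088	0.154	-0.029	<0.001
Aha11	2.6	0.318	0.043	0.217	0.0081	0.138	-0.114	<0.001
Aha18	2.6	0.360	-0.015	0.386	0.0086	0.152	-0.009	0.743
Aha19	2.8	0.332	-0.084	0.027	0.0086	0.150	-0.033	<0.001
Aha21	2.7	0.404	0.075	0.075	0.0083	0.148	-0.021	0.106
Aha31	3.1	0.387	0.068	0.082	0.0093	0.157	-0.119	<0.001
AhaN1	2.9	0.465	0.081	0.030	0.0092	0.155	-0.169	<0.001
AhaN3	3.1	0.399	0.110	0.010	0.0089	0.154	-0.151	<0.001
AhaN4	2.2	0.343	0.058	0.151	0.0067	0.119	-0.103	<0.001
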