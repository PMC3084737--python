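label	risk_allele	stratum	cases_0	cases_1	cases_2	controls_0	controls_1	controls_2
rs12914385	T	smokers	1230	1973	815	373	413	121
rs12914385	T	familial	154	292	139	373	413	121
rs12914385	T	never-smokers	100	109	30	217	260	76
rs8042374	A	smokers	136	1207	2668	52	314	541
rs8042374	A	familial	16	155	413	52	314	541
rs8042374	A	never-smokers	18	86	135	33	206	314
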