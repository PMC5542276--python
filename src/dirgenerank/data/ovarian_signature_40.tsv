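gene_id	mean_coef	stability
3174	-0.611	397
2250	-0.542	400
4802	-0.517	375
27329	-0.465	400
22955	-0.460	399
3026	-0.430	393
1453	-0.422	358
3607	-0.413	392
3207	-0.332	400
2113	-0.281	240
636	-0.264	386
362	-0.235	281
8706	-0.204	314
3918	-0.203	399
3570	-0.193	299
6361	-0.185	346
1381	-0.132	399
10753	-0.130	381
8856	-0.0935	0
10563	-0.0762	31
8503	-0.0669	0
554	0.0142	0
8877	0.0616	0
646	0.10637585	391
1746	0.161	97
10894	0.190	395
2173	0.193	319
6622	0.209	391
5733	0.236	399
27129	0.253	398
56914	0.262	320
344	0.296	399
11027	0.310	396
3036	0.350	378
8904	0.367	396
324	0.406	385
7082	0.456	400
2022	0.4778	356
1176	0.510	397
3562	0.887	329
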