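subject	aetiology	seizure_type_pre	seizure_type_post	uncoupling	amp_pre_uV	amp_post_uV	channels_peak_pre	channels_peak_post
12	Focal lesion	NVD	NVD	Unknown	91	49	4	1
13	HIE grade 2	NVD	NVD	Unknown	123	138	2	2
16	Stroke	NVD	NVD	Unknown	93.5	55.5	5	4
1	HIE grade 2	EG	EG	NO	485	63	8	1
4	HIE grade 3	EG	EG	NO	146	149	8	8
5	HIE grade 3	EG	EG	NO	180	42	8	6
6	Meningitis	EG	EG	NO	165	93	8	8
7	HIE grade 3	EG	EG	NO	67.5	36.5	5	4
8	Contusion post forceps	EG	EG	NO	61	68	1	2
11	HIE grade 3	EG	EG	NO	63	51.5	2	1.5
14	HIE grade 3	EG	EG	NO	315	190	8	2
15	HIE grade 3	EG	EG	NO	53.5	37	3	3
17	HIE grade 3	EC/EG	EC/EG	NO	47.5	50	3	4
2	HIE grade 2	EC	EG	YES	40	20	4	1
3	HIE grade 2	EC	EG	YES	339	49	8	1
9	Stroke	EC	EG	YES	321	47.5	3.8	3
10	Stroke	EC	EG	YES	195	88	4	4
18	Stroke	EC	EG	YES	123	70	4	4
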