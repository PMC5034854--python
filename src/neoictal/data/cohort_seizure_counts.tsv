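patient	aetiology	n_pre	n_post	dose1_mg_kg	dose2_mg_kg
1	HIE grade 2	7	7	20
2	HIE grade 2	3	3	20
3	HIE grade 2	6	6	20
4	HIE grade 3	8	8	20
5	HIE grade 3	25	25	20
6	Meningitis	3	3	20
7	HIE grade 3	66	66	20	10
8	Contusion post forceps	1	1	20
9	Stroke	2	2	20
10	Stroke	11	11	20
11	HIE grade 3	4	4	20
12	Focal lesion	1	1	20
13	HIE grade 2	5	5	20
14	HIE grade 3	1	1	20
15	HIE grade 3	68	68	20	10
16	Stroke	6	6	20
17	HIE grade 3	6	6	20
18	Stroke	39	39	20	10
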