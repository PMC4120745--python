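subgroup	lineage	n_seqs	rt_identity_pct	type_subtype	domain	length_aa	aa_identity_pct	top_hit	probability_pct	n_copies
L2_1	L2	13	82.2	V	none					
L2_2	L2	16	58.2	IC	PHD	50	30.0	3zpv_A	98.2	
L2_2	L2	16	58.2	IC	RRM	155	26.0	2ghp_A	80.7	2
L2_2	L2	16	58.2	IC	CCHC	67	46.1	PTHR23002	98.5	3
L2_3	L2	43	57.6	IIA	Tnp22	158	30.6	2yko_A	100.0	1
L2_4	L2	7	64.8	IIIA	PHD	51	43.0	2vpb_A	99.7	
L2_5	L2	8	52.2	IIB	Tnp22	208	27.7	2yko_A	100.0	1
L2_5	L2	8	52.2	IIB	PHD	55	29.1	3lqh_A	99.7	
L2_6	L2	23	55.9	IIC	PHD	51	42.5	2vpb_A	96.6	
L2_6	L2	23	55.9	IIC	Tnp22	209	35.5	2yko_A	100.0	1
L2_7	L2	7	50.3	IIA	Tnp22	191	21.7	2yko_A	100.0	1
L2_8	L2	4	62.7	IC	RRM	188	34.5	3smz_A	86.7	2
L2_8	L2	4	62.7	IC	CCHC	60	45.3	PTHR23002	99.2	3
L2_9	L2	4	57.1	IVA	Esterase	176	28.0	3p94_A	99.9	
L2_10	L2	2	79.0	IA	RRM	63	85.9	2lkz_A	90.2	
L2_10	L2	2	79.0	IA	CCHC	64	76.9	PTHR23002	98.9	
Jockey_1	Jockey	75	51.8	IB	RRM	143	29.1	2cjk_A	96.6	2
Jockey_1	Jockey	75	51.8	IB	CCHC	55	46.2	PTHR23002	98.9	3
Jockey_2	Jockey	12	51.6	IA	RRM	74	32.5	2lxi	93.8	1
Jockey_2	Jockey	12	51.6	IA	CCHC	54	39.4	PTHR23002	98.8	3
CR1_1	CR1	22	53.5	IIA	Tnp22	186	23.5	2yko_A	98.5	1
CR1_2	CR1	11	70.0	V	PHD	50	41.3	2vpb_A	94.6	
CR1_3	CR1	8	58.8	IC	PHD	53	48.1	2vpb_A	96.3	
CR1_3	CR1	8	58.8	IC	CC	34	22.3			
CR1_3	CR1	8	58.8	IC	RRM	144	37.1	1b7f_A	93.8	2
CR1_3	CR1	8	58.8	IC	CCHC	65	46.8	PTHR23002	98.3	3
CR1_4	CR1	112	53.1	IIIB	PHD	53	27.6	3zpv_A	95.0	
CR1_4	CR1	112	53.1	IIIB	RRM	53	28.4	2dhg_A	79.4	1
CR1_5	CR1	3	58.1	IIC	PHD	50	71.9	2vpb_A	99.4	
CR1_5	CR1	3	58.1	IIC	Tnp22	129	41.8	2yko_A	63.1	1
CR1_6	CR1	18	54.0	IIIA	PHD	48	40.6	1wep_A	99.4	
CR1_7	CR1	56	62.9	IVB	lz	44	34.0	2yon_A	85.1	
CR1_7	CR1	56	62.9	IVB	zf	44	34.0	2gmg_A	37.1	
CR1_7	CR1	56	62.9	IVB	Esterase	174	43.5	2waa_A	99.7	
CR1_8	CR1	4	61.5		Tnp22	175	36.5	2yko_A	100.0	
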