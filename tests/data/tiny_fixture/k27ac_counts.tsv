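name	K27ac_D35_WT_r1	K27ac_D35_WT_r2	K27ac_D35_WT_r3	K27ac_D35_WT_r4	K27ac_D35_HET_r1	K27ac_D35_HET_r2	K27ac_D35_HET_r3	K27ac_D35_HET_r4
peak0000	51	78	41	67	17	15	22	19
peak0001	44	42	37	38	9	6	15	16
peak0002	62	117	61	89	24	20	30	37
peak0003	120	129	137	133	35	25	39	40
peak0004	129	245	174	145	35	41	40	50
peak0005	96	67	89	99	493	493	583	530
peak0006	88	72	110	78	341	233	423	277
peak0007	83	53	80	48	263	264	226	241
peak0008	99	221	135	157	637	550	734	851
peak0009	155	215	252	251	872	656	719	741
peak0022	106	88	120	104	100	129	121	127
peak0024	51	53	33	55	67	58	65	68
peak0025	86	65	83	74	90	69	60	65
peak0026	255	167	263	225	151	202	251	127
peak0027	96	100	150	86	125	92	75	85
peak0034	67	27	28	39	49	41	44	38
peak0035	154	139	86	136	84	115	132	94
peak0037	76	78	79	58	57	78	43	85
peak0038	70	37	61	83	59	84	95	51
peak0041	106	53	111	70	92	111	86	94
peak0043	72	60	72	58	63	71	107	58
peak0044	155	129	58	183	91	143	157	140
peak0045	67	170	89	95	123	92	94	77
peak0046	67	56	81	64	73	98	68	54
peak0048	119	116	88	197	71	150	116	95
peak0049	115	141	154	79	209	124	254	142
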