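gene_id	RNA_WT_D0_r1	RNA_WT_D0_r2	RNA_WT_D0_r3	RNA_WT_D0_r4	RNA_WT_D15_r1	RNA_WT_D15_r2	RNA_WT_D15_r3	RNA_WT_D15_r4	RNA_WT_D35_r1	RNA_WT_D35_r2	RNA_WT_D35_r3	RNA_WT_D35_r4	RNA_HET_D0_r1	RNA_HET_D0_r2	RNA_HET_D0_r3	RNA_HET_D0_r4	RNA_HET_D15_r1	RNA_HET_D15_r2	RNA_HET_D15_r3	RNA_HET_D15_r4	RNA_HET_D35_r1	RNA_HET_D35_r2	RNA_HET_D35_r3	RNA_HET_D35_r4
g0000	29	29	21	46	54	59	99	53	107	110	123	115	24	23	27	22	106	83	68	82	152	103	87	69
g0001	60	57	50	46	8	7	9	9	13	14	14	5	47	35	60	71	15	10	5	12	18	16	7	15
g0002	289	279	206	248	406	216	238	238	772	928	824	1255	266	260	297	226	256	340	273	198	811	976	650	942
g0003	69	57	71	81	219	258	296	183	24	28	31	29	65	110	81	52	340	248	264	183	15	16	23	24
g0004	32	35	41	66	59	25	51	38	192	137	226	210	45	37	51	52	26	53	50	26	916	601	389	568
g0005	54	66	51	50	13	6	17	16	40	47	33	51	51	72	65	60	14	12	13	15	49	83	51	40
g0006	50	26	12	23	244	188	217	210	11	17	14	15	25	21	31	13	162	245	212	247	7	13	19	12
g0007	65	64	74	46	84	65	38	73	648	440	612	864	57	57	43	33	67	55	78	59	469	763	560	566
g0008	13	16	11	10	0	2	1	1	37	34	50	45	7	8	9	14	5	2	5	0	39	35	36	41
g0009	41	104	43	102	575	526	410	625	597	437	461	554	62	61	85	65	706	542	522	563	410	608	416	618
g0010	46	46	59	62	139	187	139	167	46	61	69	73	60	79	82	55	196	179	174	175	94	86	51	60
g0011	247	214	362	307	2574	2742	2243	1846	558	365	647	557	296	245	240	256	1546	1987	1992	1402	380	464	540	455
g0012	357	337	225	392	293	360	331	246	804	1000	940	1456	265	337	240	259	339	306	236	256	4119	3530	3155	3657
g0013	102	90	70	75	14	15	16	16	14	13	19	28	104	56	83	118	34	8	19	17	19	19	22	16
g0014	10	11	15	13	30	30	31	24	8	13	8	10	10	28	12	9	42	44	32	39	6	18	12	15
g0015	511	395	288	488	1247	1561	1395	1221	2889	1875	1782	1405	390	568	449	516	1248	1703	921	1184	1940	1770	1575	2913
g0016	35	33	42	23	24	28	30	26	171	168	166	123	16	43	37	39	30	31	27	33	562	496	747	588
g0017	178	179	165	129	1278	1181	1154	1361	1321	1455	830	1303	79	141	139	114	1222	608	871	1579	2004	1798	1231	984
g0018	32	26	32	46	101	69	78	107	104	120	150	171	32	41	32	37	110	95	111	131	182	185	104	196
g0019	29	28	21	16	161	135	190	174	9	14	2	6	35	19	25	19	165	215	158	110	5	12	15	9
g0020	19	33	23	26	2	5	8	9	38	30	41	23	35	21	17	19	18	5	6	5	25	29	25	27
g0021	23	28	41	23	143	127	328	299	131	227	98	226	29	21	34	30	217	158	166	208	160	149	179	294
g0022	89	107	78	79	189	164	193	250	23	17	30	12	47	57	78	61	245	171	152	261	21	20	18	9
g0023	59	54	27	48	117	174	182	156	19	23	9	7	60	48	59	63	90	139	100	69	11	12	25	12
g0024	1048	974	1088	1050	1250	688	851	498	177	276	191	257	879	922	882	893	688	753	949	742	76	63	62	75
g0025	3	7	3	6	6	7	3	2	91	84	79	95	7	9	10	7	4	11	3	13	87	76	96	116
g0026	41	25	74	67	26	12	16	18	18	18	13	7	57	48	65	55	13	5	8	21	8	20	5	8
g0027	7	15	18	23	189	183	142	116	115	124	174	108	18	21	24	20	109	129	220	117	124	121	139	161
g0028	109	103	109	109	302	386	240	231	33	39	19	23	103	93	102	90	373	280	250	492	28	33	25	34
g0029	7	4	4	9	12	14	21	28	3	1	0	1	6	8	5	10	25	9	25	20	1	0	1	1
g0030	36	35	44	22	8	11	13	14	44	46	40	47	35	28	20	18	8	6	10	9	49	15	26	42
g0031	60	41	73	85	156	185	144	105	39	89	51	54	78	64	65	86	251	131	243	237	76	45	77	67
g0032	14	15	9	11	36	35	39	30	12	14	16	15	7	11	10	11	23	25	28	23	10	11	13	8
g0033	131	155	108	119	271	625	339	413	588	602	504	433	181	99	131	145	554	319	507	517	520	320	863	575
g0034	99	74	75	63	15	10	17	11	10	19	19	9	104	100	28	54	10	13	14	16	13	10	26	16
g0035	115	155	136	118	1769	1008	1116	1293	68	61	36	109	104	122	136	178	844	1489	437	1305	57	69	61	55
g0036	104	113	118	141	106	110	113	122	54	35	23	31	143	102	118	198	89	161	135	109	26	44	51	29
g0037	23	19	13	14	106	214	107	109	125	186	148	225	14	13	15	15	86	132	197	118	171	186	123	157
g0038	21	6	18	17	10	3	1	1	20	26	19	22	19	23	17	16	4	7	1	5	25	18	23	27
g0039	58	20	43	31	317	254	459	283	82	78	92	83	40	68	39	38	258	206	298	458	131	53	65	95
g0040	93	133	114	96	326	224	434	218	613	525	428	719	110	91	126	73	503	318	321	265	540	534	386	479
g0041	96	94	128	128	384	216	350	330	141	101	126	143	115	88	150	86	218	222	398	321	135	154	120	91
g0042	18	14	20	34	77	52	91	75	6	14	6	6	21	34	35	29	70	72	70	83	9	3	14	10
g0043	40	19	11	38	13	10	4	7	29	48	28	19	48	13	25	19	5	7	4	4	25	43	31	30
g0044	27	17	22	17	7	4	4	5	131	85	92	117	27	16	41	18	3	7	9	5	112	87	86	143
g0045	10	23	18	16	5	2	9	8	20	39	39	27	27	26	38	22	3	9	8	7	19	27	24	34
g0046	32	46	33	42	275	225	347	165	15	20	13	12	53	38	32	45	280	403	344	256	21	31	17	18
g0047	195	228	177	102	171	188	161	107	32	53	41	36	193	164	190	253	137	212	130	154	11	13	9	9
g0048	386	499	241	307	481	439	358	402	3464	3833	4246	3946	315	236	336	267	535	461	452	366	5064	3781	3560	4085
g0049	19	34	40	30	232	180	172	251	326	201	157	232	39	39	24	24	190	259	231	344	216	167	247	199
g0050	33	40	55	37	9	9	11	7	215	105	103	175	54	54	45	41	16	6	14	7	235	200	139	161
g0051	54	66	93	80	176	152	194	200	92	68	96	70	77	92	83	43	211	285	171	233	52	90	79	109
g0052	86	75	104	65	52	109	86	59	255	396	344	302	93	90	58	84	69	48	53	83	1285	873	1241	1257
g0053	26	17	54	37	38	25	34	21	288	418	361	385	40	21	41	11	42	50	24	48	441	479	213	347
g0054	99	161	186	222	255	300	194	258	44	55	57	30	172	207	155	193	290	233	232	203	26	11	22	11
g0055	127	107	101	115	32	34	33	34	551	410	331	579	86	124	132	109	23	29	27	36	272	554	442	403
g0056	19	15	10	6	15	15	17	11	196	135	190	191	7	16	10	17	13	12	11	9	121	145	228	107
g0057	186	221	185	183	40	55	36	64	667	914	1162	728	153	321	175	130	58	72	43	63	523	773	1113	780
g0058	124	127	133	161	174	125	106	129	36	32	62	34	132	82	168	111	143	116	106	143	3	17	3	13
g0059	56	68	91	62	531	603	300	624	110	114	128	107	69	80	65	65	526	520	415	466	119	92	118	98
g0060	252	524	579	362	421	348	564	504	104	94	142	137	489	452	539	474	739	407	391	596	21	36	40	31
g0061	118	74	95	90	225	376	366	357	318	279	558	282	65	93	98	120	256	215	278	334	471	525	313	347
g0062	195	135	185	110	57	32	34	36	38	33	48	53	248	129	117	171	42	34	49	34	24	45	47	29
g0063	53	69	79	53	655	374	523	516	97	158	125	112	58	49	63	52	596	461	486	457	209	157	126	123
g0064	202	220	173	277	198	198	218	188	560	1040	728	849	127	226	203	259	191	288	201	250	3296	2584	3288	2167
g0065	48	88	98	57	18	21	30	19	15	14	19	13	55	72	43	74	18	12	31	31	28	17	15	10
g0066	17	11	21	22	28	9	23	7	183	210	188	210	15	11	27	34	13	19	13	9	219	213	251	250
g0067	129	140	227	115	32	16	57	27	567	678	450	461	87	113	120	194	34	22	30	49	774	703	758	849
g0068	13	27	15	26	197	156	153	179	52	55	60	63	17	15	24	16	149	214	196	159	46	56	63	43
g0069	15	14	9	15	102	104	107	160	7	6	3	10	10	14	16	10	168	112	122	62	4	9	8	5
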