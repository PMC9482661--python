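chr1	3522	4325	k4_g0000_r4	0	.
chr1	15738	16527	k4_g0003_r4	0	.
chr1	20802	21600	peak0007_r4	0	.
chr1	26573	27384	k4_g0006_r4	0	.
chr1	34233	35017	k4_g0007_r4	0	.
chr1	44914	45717	k4_g0009_r4	0	.
chr1	49336	50135	k4_g0010_r4	0	.
chr1	54283	55073	k4_g0011_r4	0	.
chr1	55392	56195	k4_g0012_r4	0	.
chr1	62366	63172	k4_g0014_r4	0	.
chr1	71216	72039	k4_g0015_r4	0	.
chr1	72578	73386	k4_g0016_r4	0	.
chr1	72675	73487	peak0008_r4	0	.
chr1	75245	76045	noise_H3K4me3_D15_WT_r4_2	0	.
chr1	77789	78579	k4_g0017_r4	0	.
chr1	86745	87568	k4_g0018_r4	0	.
chr1	99766	100574	k4_g0021_r4	0	.
chr1	103768	104572	k4_g0022_r4	0	.
chr1	108588	109393	k4_g0023_r4	0	.
chr1	117930	118752	k4_g0025_r4	0	.
chr1	125659	126466	k4_g0027_r4	0	.
chr1	128585	129385	noise_H3K4me3_D15_WT_r4_1	0	.
chr1	130444	131259	k4_g0028_r4	0	.
chr1	132015	132818	k4_g0029_r4	0	.
chr1	136143	136943	noise_H3K4me3_D15_WT_r4_0	0	.
chr1	140888	141688	noise_H3K4me3_D15_WT_r4_3	0	.
chr1	143157	143955	k4_g0031_r4	0	.
chr1	144766	145553	k4_g0032_r4	0	.
chr1	152359	153167	k4_g0033_r4	0	.
chr1	161170	161969	k4_g0035_r4	0	.
chr1	162693	163509	k4_g0036_r4	0	.
chr1	167979	168765	k4_g0037_r4	0	.
chr1	181543	182318	k4_g0039_r4	0	.
chr1	181599	182398	peak0050_r4	0	.
chr1	185951	186746	k4_g0040_r4	0	.
chr1	187894	188661	k4_g0041_r4	0	.
chr1	191213	191998	k4_g0042_r4	0	.
chr1	191325	192122	peak0029_r4	0	.
chr2	3380	4192	peak0051_r4	0	.
chr2	14395	15213	k4_g0046_r4	0	.
chr2	18658	19460	k4_g0047_r4	0	.
chr2	19996	20768	k4_g0048_r4	0	.
chr2	27747	28543	k4_g0049_r4	0	.
chr2	41533	42326	k4_g0052_r4	0	.
chr2	43393	44184	k4_g0053_r4	0	.
chr2	47861	48670	peak0000_r4	0	.
chr2	59558	60351	k4_g0056_r4	0	.
chr2	67627	68410	peak0004_r4	0	.
chr2	67704	68507	k4_g0058_r4	0	.
chr2	69504	70307	k4_g0059_r4	0	.
chr2	76066	76844	k4_g0060_r4	0	.
chr2	77090	77891	k4_g0061_r4	0	.
chr2	88650	89455	k4_g0063_r4	0	.
chr2	94329	95138	k4_g0064_r4	0	.
chr2	103088	103880	k4_g0066_r4	0	.
chr2	110554	111380	k4_g0068_r4	0	.
chr2	117538	118354	k4_g0069_r4	0	.
chr2	117588	118354	peak0049_r4	0	.
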