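chr1	7479	8275	k4_g0001_r2	0	.
chr1	11814	12592	k4_g0002_r2	0	.
chr1	15726	16546	k4_g0003_r2	0	.
chr1	20696	21507	k4_g0004_r2	0	.
chr1	20793	21609	peak0007_r2	0	.
chr1	25037	25842	k4_g0005_r2	0	.
chr1	26575	27348	k4_g0006_r2	0	.
chr1	36002	36795	k4_g0008_r2	0	.
chr1	44929	45709	k4_g0009_r2	0	.
chr1	54290	55076	k4_g0011_r2	0	.
chr1	55371	56189	k4_g0012_r2	0	.
chr1	61098	61910	k4_g0013_r2	0	.
chr1	62349	63171	k4_g0014_r2	0	.
chr1	65091	65891	noise_H3K4me3_D0_HET_r2_1	0	.
chr1	72596	73381	k4_g0016_r2	0	.
chr1	72679	73498	peak0008_r2	0	.
chr1	77774	78586	k4_g0017_r2	0	.
chr1	77799	78579	peak0015_r2	0	.
chr1	86741	87555	k4_g0018_r2	0	.
chr1	90030	90827	k4_g0019_r2	0	.
chr1	94465	95292	k4_g0020_r2	0	.
chr1	99763	100554	k4_g0021_r2	0	.
chr1	103767	104580	k4_g0022_r2	0	.
chr1	108596	109384	k4_g0023_r2	0	.
chr1	110934	111737	k4_g0024_r2	0	.
chr1	117952	118720	k4_g0025_r2	0	.
chr1	120306	121124	k4_g0026_r2	0	.
chr1	125638	126463	k4_g0027_r2	0	.
chr1	130440	131247	k4_g0028_r2	0	.
chr1	132016	132819	k4_g0029_r2	0	.
chr1	138212	139019	k4_g0030_r2	0	.
chr1	143157	143951	k4_g0031_r2	0	.
chr1	144748	145555	k4_g0032_r2	0	.
chr1	152351	153147	k4_g0033_r2	0	.
chr1	156804	157610	k4_g0034_r2	0	.
chr1	161154	161970	k4_g0035_r2	0	.
chr1	162720	163489	k4_g0036_r2	0	.
chr1	168001	168789	k4_g0037_r2	0	.
chr1	171158	171958	noise_H3K4me3_D0_HET_r2_3	0	.
chr1	175290	176115	k4_g0038_r2	0	.
chr1	181501	182321	k4_g0039_r2	0	.
chr1	181587	182393	peak0050_r2	0	.
chr1	185961	186747	k4_g0040_r2	0	.
chr1	187900	188692	k4_g0041_r2	0	.
chr1	191226	192031	k4_g0042_r2	0	.
chr1	191318	192137	peak0029_r2	0	.
chr2	3412	4230	k4_g0043_r2	0	.
chr2	4879	5688	k4_g0044_r2	0	.
chr2	8020	8832	k4_g0045_r2	0	.
chr2	14413	15204	k4_g0046_r2	0	.
chr2	18632	19445	k4_g0047_r2	0	.
chr2	19998	20790	k4_g0048_r2	0	.
chr2	27759	28548	k4_g0049_r2	0	.
chr2	30037	30841	k4_g0050_r2	0	.
chr2	38106	38917	k4_g0051_r2	0	.
chr2	43399	44189	k4_g0053_r2	0	.
chr2	47860	48643	peak0000_r2	0	.
chr2	47887	48685	k4_g0054_r2	0	.
chr2	52659	53463	k4_g0055_r2	0	.
chr2	59567	60358	k4_g0056_r2	0	.
chr2	61272	62086	k4_g0057_r2	0	.
chr2	67631	68410	peak0004_r2	0	.
chr2	67730	68535	k4_g0058_r2	0	.
chr2	69498	70293	k4_g0059_r2	0	.
chr2	76075	76856	k4_g0060_r2	0	.
chr2	78910	79710	noise_H3K4me3_D0_HET_r2_2	0	.
chr2	88679	89445	k4_g0063_r2	0	.
chr2	94327	95139	k4_g0064_r2	0	.
chr2	96093	96896	k4_g0065_r2	0	.
chr2	101473	102273	noise_H3K4me3_D0_HET_r2_0	0	.
chr2	110572	111363	k4_g0068_r2	0	.
chr2	117541	118342	k4_g0069_r2	0	.
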