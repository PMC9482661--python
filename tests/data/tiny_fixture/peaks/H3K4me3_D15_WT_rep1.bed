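chr1	3527	4315	k4_g0000_r1	0	.
chr1	11805	12595	k4_g0002_r1	0	.
chr1	15721	16553	k4_g0003_r1	0	.
chr1	20677	21496	k4_g0004_r1	0	.
chr1	26565	27353	k4_g0006_r1	0	.
chr1	34210	35033	k4_g0007_r1	0	.
chr1	44916	45697	k4_g0009_r1	0	.
chr1	49319	50134	k4_g0010_r1	0	.
chr1	54275	55084	k4_g0011_r1	0	.
chr1	55378	56180	k4_g0012_r1	0	.
chr1	62363	63162	k4_g0014_r1	0	.
chr1	71212	72015	k4_g0015_r1	0	.
chr1	72579	73376	k4_g0016_r1	0	.
chr1	72666	73461	peak0008_r1	0	.
chr1	77777	78565	k4_g0017_r1	0	.
chr1	86738	87551	k4_g0018_r1	0	.
chr1	90049	90841	k4_g0019_r1	0	.
chr1	98415	99215	noise_H3K4me3_D15_WT_r1_2	0	.
chr1	99765	100553	k4_g0021_r1	0	.
chr1	108599	109415	k4_g0023_r1	0	.
chr1	110935	111735	k4_g0024_r1	0	.
chr1	117926	118718	k4_g0025_r1	0	.
chr1	120403	121198	peak0042_r1	0	.
chr1	125649	126453	k4_g0027_r1	0	.
chr1	130442	131247	k4_g0028_r1	0	.
chr1	132022	132821	k4_g0029_r1	0	.
chr1	143187	143981	k4_g0031_r1	0	.
chr1	144772	145555	k4_g0032_r1	0	.
chr1	152355	153168	k4_g0033_r1	0	.
chr1	161176	161979	k4_g0035_r1	0	.
chr1	167992	168800	k4_g0037_r1	0	.
chr1	181519	182306	k4_g0039_r1	0	.
chr1	181588	182391	peak0050_r1	0	.
chr1	185967	186750	k4_g0040_r1	0	.
chr1	187879	188686	k4_g0041_r1	0	.
chr1	191232	192013	k4_g0042_r1	0	.
chr2	3402	4192	peak0051_r1	0	.
chr2	14401	15219	k4_g0046_r1	0	.
chr2	18646	19461	k4_g0047_r1	0	.
chr2	19987	20778	k4_g0048_r1	0	.
chr2	27740	28567	k4_g0049_r1	0	.
chr2	36419	37219	noise_H3K4me3_D15_WT_r1_1	0	.
chr2	38104	38925	k4_g0051_r1	0	.
chr2	41545	42326	k4_g0052_r1	0	.
chr2	43414	44189	k4_g0053_r1	0	.
chr2	47836	48656	peak0000_r1	0	.
chr2	47879	48692	k4_g0054_r1	0	.
chr2	59544	60337	k4_g0056_r1	0	.
chr2	67629	68425	peak0004_r1	0	.
chr2	67732	68530	k4_g0058_r1	0	.
chr2	69497	70297	k4_g0059_r1	0	.
chr2	76064	76858	k4_g0060_r1	0	.
chr2	77115	77894	k4_g0061_r1	0	.
chr2	88672	89470	k4_g0063_r1	0	.
chr2	94352	95124	k4_g0064_r1	0	.
chr2	103084	103890	k4_g0066_r1	0	.
chr2	110554	111374	k4_g0068_r1	0	.
chr2	117544	118368	k4_g0069_r1	0	.
chr2	117575	118397	peak0049_r1	0	.
chr2	124327	125127	noise_H3K4me3_D15_WT_r1_3	0	.
chr2	143149	143949	noise_H3K4me3_D15_WT_r1_0	0	.
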