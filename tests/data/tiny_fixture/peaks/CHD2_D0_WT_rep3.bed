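chr1	3659	4088	peak0032_r3	0	.
chr1	16000	16406	peak0035_r3	0	.
chr1	21015	21406	peak0007_r3	0	.
chr1	23831	24231	noise_CHD2_D0_WT_r3_3	0	.
chr1	26786	27172	peak0046_r3	0	.
chr1	49649	50049	peak0034_r3	0	.
chr1	71510	71899	peak0031_r3	0	.
chr1	72871	73284	peak0008_r3	0	.
chr1	78009	78386	peak0015_r3	0	.
chr1	100061	100446	peak0048_r3	0	.
chr1	111083	111501	peak0003_r3	0	.
chr1	125731	126129	peak0039_r3	0	.
chr1	130520	130927	peak0038_r3	0	.
chr1	132321	132723	peak0013_r3	0	.
chr1	138394	138794	peak0011_r3	0	.
chr1	139840	140240	noise_CHD2_D0_WT_r3_1	0	.
chr1	143495	143890	peak0012_r3	0	.
chr1	168215	168605	peak0014_r3	0	.
chr1	181804	182189	peak0050_r3	0	.
chr1	191539	191911	peak0029_r3	0	.
chr2	3612	3985	peak0051_r3	0	.
chr2	5950	6350	noise_CHD2_D0_WT_r3_0	0	.
chr2	14640	15071	peak0033_r3	0	.
chr2	18885	19260	peak0002_r3	0	.
chr2	41752	42133	peak0009_r3	0	.
chr2	48052	48453	peak0000_r3	0	.
chr2	52887	53302	peak0047_r3	0	.
chr2	57275	57675	noise_CHD2_D0_WT_r3_2	0	.
chr2	61377	61793	peak0036_r3	0	.
chr2	67830	68235	peak0004_r3	0	.
chr2	76344	76734	peak0001_r3	0	.
chr2	88757	89165	peak0030_r3	0	.
chr2	96293	96691	peak0010_r3	0	.
chr2	103325	103731	peak0037_r3	0	.
chr2	110721	111119	peak0028_r3	0	.
chr2	117775	118195	peak0049_r3	0	.
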