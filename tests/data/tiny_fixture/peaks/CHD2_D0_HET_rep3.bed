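chr1	3653	4068	peak0032_r3	0	.
chr1	20997	21405	peak0007_r3	0	.
chr1	26814	27194	peak0046_r3	0	.
chr1	49660	50057	peak0034_r3	0	.
chr1	71500	71882	peak0031_r3	0	.
chr1	72876	73272	peak0008_r3	0	.
chr1	79076	79476	noise_CHD2_D0_HET_r3_0	0	.
chr1	111103	111506	peak0003_r3	0	.
chr1	125743	126137	peak0039_r3	0	.
chr1	130529	130922	peak0038_r3	0	.
chr1	132311	132737	peak0013_r3	0	.
chr1	138412	138792	peak0011_r3	0	.
chr1	161663	162063	noise_CHD2_D0_HET_r3_3	0	.
chr1	168200	168599	peak0014_r3	0	.
chr1	181790	182208	peak0050_r3	0	.
chr1	194890	195290	noise_CHD2_D0_HET_r3_1	0	.
chr2	12873	13273	noise_CHD2_D0_HET_r3_2	0	.
chr2	14668	15061	peak0033_r3	0	.
chr2	18885	19261	peak0002_r3	0	.
chr2	41739	42145	peak0009_r3	0	.
chr2	48043	48441	peak0000_r3	0	.
chr2	52899	53302	peak0047_r3	0	.
chr2	61403	61775	peak0036_r3	0	.
chr2	67824	68203	peak0004_r3	0	.
chr2	88740	89163	peak0030_r3	0	.
chr2	96284	96690	peak0010_r3	0	.
chr2	103348	103745	peak0037_r3	0	.
chr2	110728	111133	peak0028_r3	0	.
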