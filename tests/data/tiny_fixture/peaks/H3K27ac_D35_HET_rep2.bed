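chr1	11757	12352	peak0022_r2	0	.
chr1	15889	16508	peak0035_r2	0	.
chr1	20908	21520	peak0007_r2	0	.
chr1	25078	25678	noise_H3K27ac_D35_HET_r2_3	0	.
chr1	26725	27303	peak0046_r2	0	.
chr1	36264	36842	peak0027_r2	0	.
chr1	45088	45714	peak0043_r2	0	.
chr1	49548	50183	peak0034_r2	0	.
chr1	55572	56158	peak0005_r2	0	.
chr1	61162	61745	peak0026_r2	0	.
chr1	72779	73374	peak0008_r2	0	.
chr1	94504	95112	peak0025_r2	0	.
chr1	99950	100541	peak0048_r2	0	.
chr1	103732	104345	peak0024_r2	0	.
chr1	108570	109185	peak0045_r2	0	.
chr1	110996	111605	peak0003_r2	0	.
chr1	130409	131009	peak0038_r2	0	.
chr1	157639	158239	noise_H3K27ac_D35_HET_r2_0	0	.
chr1	172645	173245	noise_H3K27ac_D35_HET_r2_1	0	.
chr2	3489	4102	peak0051_r2	0	.
chr2	6021	6621	noise_H3K27ac_D35_HET_r2_2	0	.
chr2	18791	19371	peak0002_r2	0	.
chr2	41641	42235	peak0009_r2	0	.
chr2	67721	68328	peak0004_r2	0	.
chr2	76245	76845	peak0001_r2	0	.
chr2	94473	95079	peak0006_r2	0	.
chr2	103227	103849	peak0037_r2	0	.
chr2	117682	118307	peak0049_r2	0	.
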