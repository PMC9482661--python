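chr1	11755	12350	peak0022_r3	0	.
chr1	15906	16494	peak0035_r3	0	.
chr1	20898	21501	peak0007_r3	0	.
chr1	36240	36837	peak0027_r3	0	.
chr1	45112	45729	peak0043_r3	0	.
chr1	49548	50160	peak0034_r3	0	.
chr1	55568	56162	peak0005_r3	0	.
chr1	61136	61755	peak0026_r3	0	.
chr1	72783	73384	peak0008_r3	0	.
chr1	99936	100561	peak0048_r3	0	.
chr1	103736	104333	peak0024_r3	0	.
chr1	108569	109159	peak0045_r3	0	.
chr1	127554	128154	noise_H3K27ac_D35_WT_r3_1	0	.
chr1	130406	131006	peak0038_r3	0	.
chr1	175860	176460	noise_H3K27ac_D35_WT_r3_2	0	.
chr2	3508	4083	peak0051_r3	0	.
chr2	18776	19375	peak0002_r3	0	.
chr2	27780	28375	peak0041_r3	0	.
chr2	41634	42239	peak0009_r3	0	.
chr2	43535	44132	peak0044_r3	0	.
chr2	67721	68317	peak0004_r3	0	.
chr2	76230	76842	peak0001_r3	0	.
chr2	94473	95069	peak0006_r3	0	.
chr2	103229	103824	peak0037_r3	0	.
chr2	113289	113889	noise_H3K27ac_D35_WT_r3_3	0	.
chr2	117684	118269	peak0049_r3	0	.
chr2	121005	121605	noise_H3K27ac_D35_WT_r3_0	0	.
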