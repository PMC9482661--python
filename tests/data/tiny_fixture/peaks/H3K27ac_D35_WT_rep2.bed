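chr1	85	685	noise_H3K27ac_D35_WT_r2_2	0	.
chr1	11764	12368	peak0022_r2	0	.
chr1	15916	16489	peak0035_r2	0	.
chr1	20913	21492	peak0007_r2	0	.
chr1	36246	36849	peak0027_r2	0	.
chr1	45113	45699	peak0043_r2	0	.
chr1	49566	50151	peak0034_r2	0	.
chr1	55578	56152	peak0005_r2	0	.
chr1	61140	61745	peak0026_r2	0	.
chr1	66599	67199	noise_H3K27ac_D35_WT_r2_1	0	.
chr1	72767	73380	peak0008_r2	0	.
chr1	94489	95101	peak0025_r2	0	.
chr1	99953	100534	peak0048_r2	0	.
chr1	103721	104341	peak0024_r2	0	.
chr1	108591	109169	peak0045_r2	0	.
chr1	110979	111626	peak0003_r2	0	.
chr1	130405	130996	peak0038_r2	0	.
chr2	3506	4100	peak0051_r2	0	.
chr2	18767	19378	peak0002_r2	0	.
chr2	27804	28374	peak0041_r2	0	.
chr2	41625	42230	peak0009_r2	0	.
chr2	43554	44146	peak0044_r2	0	.
chr2	47970	48558	peak0000_r2	0	.
chr2	55881	56481	noise_H3K27ac_D35_WT_r2_0	0	.
chr2	67711	68310	peak0004_r2	0	.
chr2	76245	76861	peak0001_r2	0	.
chr2	85516	86116	noise_H3K27ac_D35_WT_r2_3	0	.
chr2	94435	95063	peak0006_r2	0	.
chr2	103221	103841	peak0037_r2	0	.
chr2	117672	118278	peak0049_r2	0	.
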