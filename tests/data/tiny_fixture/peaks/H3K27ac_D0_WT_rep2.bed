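chr1	3570	4160	peak0032_r2	0	.
chr1	15891	16494	peak0035_r2	0	.
chr1	20923	21501	peak0007_r2	0	.
chr1	26677	27305	peak0046_r2	0	.
chr1	49552	50166	peak0034_r2	0	.
chr1	57135	57735	noise_H3K27ac_D0_WT_r2_3	0	.
chr1	71392	72017	peak0031_r2	0	.
chr1	72778	73380	peak0008_r2	0	.
chr1	77893	78505	peak0015_r2	0	.
chr1	79296	79896	noise_H3K27ac_D0_WT_r2_2	0	.
chr1	99948	100549	peak0048_r2	0	.
chr1	111000	111593	peak0003_r2	0	.
chr1	130424	131015	peak0038_r2	0	.
chr1	132236	132836	peak0013_r2	0	.
chr1	143394	144003	peak0012_r2	0	.
chr1	191416	192019	peak0029_r2	0	.
chr1	197953	198553	noise_H3K27ac_D0_WT_r2_0	0	.
chr2	18783	19389	peak0002_r2	0	.
chr2	41641	42237	peak0009_r2	0	.
chr2	47958	48561	peak0000_r2	0	.
chr2	76246	76840	peak0001_r2	0	.
chr2	84535	85135	noise_H3K27ac_D0_WT_r2_1	0	.
chr2	96182	96796	peak0010_r2	0	.
chr2	103250	103836	peak0037_r2	0	.
chr2	110639	111223	peak0028_r2	0	.
chr2	117688	118280	peak0049_r2	0	.
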