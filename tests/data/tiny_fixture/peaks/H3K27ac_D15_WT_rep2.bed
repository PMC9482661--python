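chr1	3545	4147	peak0032_r2	0	.
chr1	20913	21502	peak0007_r2	0	.
chr1	26694	27303	peak0046_r2	0	.
chr1	45109	45728	peak0043_r2	0	.
chr1	54474	55066	peak0020_r2	0	.
chr1	55556	56174	peak0005_r2	0	.
chr1	71410	72009	peak0031_r2	0	.
chr1	72789	73380	peak0008_r2	0	.
chr1	99951	100547	peak0048_r2	0	.
chr1	108569	109169	peak0045_r2	0	.
chr1	111009	111604	peak0003_r2	0	.
chr1	116437	117037	noise_H3K27ac_D15_WT_r2_1	0	.
chr1	136346	136946	noise_H3K27ac_D15_WT_r2_0	0	.
chr1	155265	155865	noise_H3K27ac_D15_WT_r2_2	0	.
chr1	162724	163313	peak0016_r2	0	.
chr1	191418	192014	peak0029_r2	0	.
chr2	8051	8655	peak0019_r2	0	.
chr2	18777	19383	peak0002_r2	0	.
chr2	27796	28381	peak0041_r2	0	.
chr2	41640	42233	peak0009_r2	0	.
chr2	43549	44129	peak0044_r2	0	.
chr2	47944	48556	peak0000_r2	0	.
chr2	67736	68315	peak0004_r2	0	.
chr2	76236	76836	peak0001_r2	0	.
chr2	88662	89263	peak0030_r2	0	.
chr2	108768	109356	peak0017_r2	0	.
chr2	110647	111235	peak0028_r2	0	.
chr2	143496	144096	noise_H3K27ac_D15_WT_r2_3	0	.
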