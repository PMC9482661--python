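chr1	3551	4153	peak0032_r1	0	.
chr1	20894	21508	peak0007_r1	0	.
chr1	26687	27300	peak0046_r1	0	.
chr1	45106	45705	peak0043_r1	0	.
chr1	54457	55061	peak0020_r1	0	.
chr1	55569	56186	peak0005_r1	0	.
chr1	72779	73363	peak0008_r1	0	.
chr1	97630	98230	noise_H3K27ac_D15_WT_r1_1	0	.
chr1	99973	100538	peak0048_r1	0	.
chr1	108569	109182	peak0045_r1	0	.
chr1	162721	163301	peak0016_r1	0	.
chr1	191411	192034	peak0029_r1	0	.
chr2	8048	8664	peak0019_r1	0	.
chr2	17604	18204	noise_H3K27ac_D15_WT_r1_2	0	.
chr2	18765	19380	peak0002_r1	0	.
chr2	27780	28392	peak0041_r1	0	.
chr2	41645	42254	peak0009_r1	0	.
chr2	43538	44129	peak0044_r1	0	.
chr2	47966	48559	peak0000_r1	0	.
chr2	67716	68315	peak0004_r1	0	.
chr2	70610	71210	noise_H3K27ac_D15_WT_r1_0	0	.
chr2	76252	76834	peak0001_r1	0	.
chr2	88671	89258	peak0030_r1	0	.
chr2	108770	109365	peak0017_r1	0	.
chr2	117669	118272	peak0049_r1	0	.
chr2	118923	119523	noise_H3K27ac_D15_WT_r1_3	0	.
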