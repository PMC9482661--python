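chr1	11759	12353	peak0022_r3	0	.
chr1	15912	16483	peak0035_r3	0	.
chr1	20901	21502	peak0007_r3	0	.
chr1	26701	27284	peak0046_r3	0	.
chr1	36252	36828	peak0027_r3	0	.
chr1	45113	45700	peak0043_r3	0	.
chr1	49544	50162	peak0034_r3	0	.
chr1	61158	61754	peak0026_r3	0	.
chr1	72784	73373	peak0008_r3	0	.
chr1	90993	91593	noise_H3K27ac_D35_HET_r3_2	0	.
chr1	94511	95088	peak0025_r3	0	.
chr1	99961	100550	peak0048_r3	0	.
chr1	103753	104347	peak0024_r3	0	.
chr1	105421	106021	noise_H3K27ac_D35_HET_r3_1	0	.
chr1	108578	109186	peak0045_r3	0	.
chr1	110982	111617	peak0003_r3	0	.
chr1	130426	131021	peak0038_r3	0	.
chr2	3483	4097	peak0051_r3	0	.
chr2	18780	19368	peak0002_r3	0	.
chr2	27776	28383	peak0041_r3	0	.
chr2	43550	44125	peak0044_r3	0	.
chr2	47953	48562	peak0000_r3	0	.
chr2	67729	68340	peak0004_r3	0	.
chr2	73317	73917	noise_H3K27ac_D35_HET_r3_3	0	.
chr2	76254	76835	peak0001_r3	0	.
chr2	101697	102297	noise_H3K27ac_D35_HET_r3_0	0	.
chr2	103240	103826	peak0037_r3	0	.
chr2	117681	118276	peak0049_r3	0	.
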