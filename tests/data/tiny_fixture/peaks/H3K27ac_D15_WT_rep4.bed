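chr1	3558	4149	peak0032_r4	0	.
chr1	8845	9445	noise_H3K27ac_D15_WT_r4_3	0	.
chr1	20916	21497	peak0007_r4	0	.
chr1	26709	27315	peak0046_r4	0	.
chr1	45106	45716	peak0043_r4	0	.
chr1	54472	55076	peak0020_r4	0	.
chr1	55561	56171	peak0005_r4	0	.
chr1	66413	67013	noise_H3K27ac_D15_WT_r4_0	0	.
chr1	71391	72017	peak0031_r4	0	.
chr1	72779	73371	peak0008_r4	0	.
chr1	88368	88968	noise_H3K27ac_D15_WT_r4_2	0	.
chr1	91638	92238	noise_H3K27ac_D15_WT_r4_1	0	.
chr1	99945	100554	peak0048_r4	0	.
chr1	108582	109158	peak0045_r4	0	.
chr1	110997	111602	peak0003_r4	0	.
chr1	191434	192010	peak0029_r4	0	.
chr2	8058	8654	peak0019_r4	0	.
chr2	27776	28374	peak0041_r4	0	.
chr2	41643	42240	peak0009_r4	0	.
chr2	43547	44137	peak0044_r4	0	.
chr2	47961	48556	peak0000_r4	0	.
chr2	67723	68323	peak0004_r4	0	.
chr2	76246	76853	peak0001_r4	0	.
chr2	88652	89273	peak0030_r4	0	.
chr2	110635	111232	peak0028_r4	0	.
chr2	117686	118284	peak0049_r4	0	.
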