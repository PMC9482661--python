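chr1	20894	21495	peak0007_r3	0	.
chr1	26695	27299	peak0046_r3	0	.
chr1	45083	45700	peak0043_r3	0	.
chr1	54457	55063	peak0020_r3	0	.
chr1	55561	56153	peak0005_r3	0	.
chr1	59253	59853	noise_H3K27ac_D15_WT_r3_1	0	.
chr1	72771	73396	peak0008_r3	0	.
chr1	99963	100545	peak0048_r3	0	.
chr1	108598	109179	peak0045_r3	0	.
chr1	111020	111604	peak0003_r3	0	.
chr1	135478	136078	noise_H3K27ac_D15_WT_r3_0	0	.
chr1	162733	163324	peak0016_r3	0	.
chr1	185435	186035	noise_H3K27ac_D15_WT_r3_2	0	.
chr1	191433	192014	peak0029_r3	0	.
chr2	8064	8649	peak0019_r3	0	.
chr2	18772	19366	peak0002_r3	0	.
chr2	27767	28362	peak0041_r3	0	.
chr2	41629	42229	peak0009_r3	0	.
chr2	43527	44132	peak0044_r3	0	.
chr2	47959	48546	peak0000_r3	0	.
chr2	67735	68333	peak0004_r3	0	.
chr2	78519	79119	noise_H3K27ac_D15_WT_r3_3	0	.
chr2	88637	89252	peak0030_r3	0	.
chr2	108771	109378	peak0017_r3	0	.
chr2	110622	111224	peak0028_r3	0	.
chr2	117697	118299	peak0049_r3	0	.
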