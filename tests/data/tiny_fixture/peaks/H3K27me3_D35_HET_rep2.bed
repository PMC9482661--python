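chr1	20703	21697	peak0007_r2	0	.
chr1	24667	25667	noise_H3K27me3_D35_HET_r2_1	0	.
chr1	72571	73575	peak0008_r2	0	.
chr1	116088	117088	noise_H3K27me3_D35_HET_r2_3	0	.
chr1	120301	121297	peak0042_r2	0	.
chr1	181495	182498	peak0050_r2	0	.
chr2	3287	4291	peak0051_r2	0	.
chr2	47758	48742	peak0000_r2	0	.
chr2	67527	68525	peak0004_r2	0	.
chr2	82048	83048	noise_H3K27me3_D35_HET_r2_2	0	.
chr2	84124	85124	noise_H3K27me3_D35_HET_r2_0	0	.
chr2	117492	118492	peak0049_r2	0	.
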