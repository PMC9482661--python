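chr1	11560	12556	peak0022_r4	0	.
chr1	20717	21678	peak0007_r4	0	.
chr1	47315	48315	noise_H3K27me3_D35_WT_r4_0	0	.
chr1	72579	73597	peak0008_r4	0	.
chr1	83149	84149	noise_H3K27me3_D35_WT_r4_3	0	.
chr1	120300	121301	peak0042_r4	0	.
chr1	153122	154122	noise_H3K27me3_D35_WT_r4_2	0	.
chr1	197797	198797	noise_H3K27me3_D35_WT_r4_1	0	.
chr2	3292	4298	peak0051_r4	0	.
chr2	47747	48757	peak0000_r4	0	.
chr2	67539	68510	peak0004_r4	0	.
chr2	117483	118485	peak0049_r4	0	.
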