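chr1	20695	21696	peak0007_r3	0	.
chr1	77679	78697	peak0015_r3	0	.
chr1	90033	91033	noise_H3K27me3_D0_WT_r3_0	0	.
chr1	117607	118607	noise_H3K27me3_D0_WT_r3_3	0	.
chr1	146757	147757	noise_H3K27me3_D0_WT_r3_2	0	.
chr2	3302	4307	peak0051_r3	0	.
chr2	47766	48760	peak0000_r3	0	.
chr2	67525	68510	peak0004_r3	0	.
chr2	85817	86817	noise_H3K27me3_D0_WT_r3_1	0	.
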