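chr1	20703	21712	peak0007_r2	0	.
chr1	77701	78674	peak0015_r2	0	.
chr1	181492	182499	peak0050_r2	0	.
chr1	184409	185409	noise_H3K27me3_D0_HET_r2_0	0	.
chr2	3316	4320	peak0051_r2	0	.
chr2	11864	12864	noise_H3K27me3_D0_HET_r2_2	0	.
chr2	47755	48757	peak0000_r2	0	.
chr2	67522	68503	peak0004_r2	0	.
chr2	78616	79616	noise_H3K27me3_D0_HET_r2_3	0	.
chr2	145593	146593	noise_H3K27me3_D0_HET_r2_1	0	.
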