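chr1	1358	2358	noise_H3K27me3_D35_HET_r1_0	0	.
chr1	11549	12549	peak0022_r1	0	.
chr1	20702	21697	peak0007_r1	0	.
chr1	41958	42958	noise_H3K27me3_D35_HET_r1_1	0	.
chr1	120292	121302	peak0042_r1	0	.
chr1	181503	182501	peak0050_r1	0	.
chr2	3291	4299	peak0051_r1	0	.
chr2	25810	26810	noise_H3K27me3_D35_HET_r1_3	0	.
chr2	67539	68530	peak0004_r1	0	.
chr2	117478	118483	peak0049_r1	0	.
chr2	138366	139366	noise_H3K27me3_D35_HET_r1_2	0	.
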