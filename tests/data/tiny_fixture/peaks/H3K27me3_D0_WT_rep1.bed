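chr1	1110	2110	noise_H3K27me3_D0_WT_r1_0	0	.
chr1	20689	21698	peak0007_r1	0	.
chr1	46627	47627	noise_H3K27me3_D0_WT_r1_1	0	.
chr1	77690	78688	peak0015_r1	0	.
chr1	181478	182493	peak0050_r1	0	.
chr2	3291	4273	peak0051_r1	0	.
chr2	35618	36618	noise_H3K27me3_D0_WT_r1_2	0	.
chr2	47754	48739	peak0000_r1	0	.
chr2	67534	68517	peak0004_r1	0	.
chr2	99338	100338	noise_H3K27me3_D0_WT_r1_3	0	.
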