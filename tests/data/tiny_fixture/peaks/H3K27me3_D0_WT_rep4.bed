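chr1	77678	78677	peak0015_r4	0	.
chr1	176911	177911	noise_H3K27me3_D0_WT_r4_2	0	.
chr1	181495	182496	peak0050_r4	0	.
chr1	185841	186841	noise_H3K27me3_D0_WT_r4_0	0	.
chr2	3300	4308	peak0051_r4	0	.
chr2	32918	33918	noise_H3K27me3_D0_WT_r4_1	0	.
chr2	138428	139428	noise_H3K27me3_D0_WT_r4_3	0	.
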