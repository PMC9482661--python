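chr1	77694	78676	peak0015_r3	0	.
chr1	127326	128326	noise_H3K27me3_D0_HET_r3_1	0	.
chr1	181494	182484	peak0050_r3	0	.
chr1	193107	194107	noise_H3K27me3_D0_HET_r3_3	0	.
chr2	3296	4306	peak0051_r3	0	.
chr2	5523	6523	noise_H3K27me3_D0_HET_r3_0	0	.
chr2	67537	68543	peak0004_r3	0	.
chr2	123863	124863	noise_H3K27me3_D0_HET_r3_2	0	.
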