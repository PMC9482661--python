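chr1	33392	34392	noise_H3K27me3_D15_WT_r4_1	0	.
chr1	120280	121300	peak0042_r4	0	.
chr1	181496	182494	peak0050_r4	0	.
chr1	191226	192225	peak0029_r4	0	.
chr2	3309	4298	peak0051_r4	0	.
chr2	47772	48771	peak0000_r4	0	.
chr2	67525	68542	peak0004_r4	0	.
chr2	105509	106509	noise_H3K27me3_D15_WT_r4_2	0	.
chr2	117476	118479	peak0049_r4	0	.
chr2	125476	126476	noise_H3K27me3_D15_WT_r4_0	0	.
chr2	131684	132684	noise_H3K27me3_D15_WT_r4_3	0	.
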