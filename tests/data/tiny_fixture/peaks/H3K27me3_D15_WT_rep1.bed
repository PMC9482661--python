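chr1	65310	66310	noise_H3K27me3_D15_WT_r1_1	0	.
chr1	72570	73586	peak0008_r1	0	.
chr1	120292	121291	peak0042_r1	0	.
chr1	176786	177786	noise_H3K27me3_D15_WT_r1_0	0	.
chr1	181500	182502	peak0050_r1	0	.
chr1	191212	192225	peak0029_r1	0	.
chr2	3290	4283	peak0051_r1	0	.
chr2	47746	48758	peak0000_r1	0	.
chr2	62926	63926	noise_H3K27me3_D15_WT_r1_2	0	.
chr2	67540	68541	peak0004_r1	0	.
chr2	117485	118495	peak0049_r1	0	.
chr2	137666	138666	noise_H3K27me3_D15_WT_r1_3	0	.
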