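chr1	67210	68210	noise_H3K27me3_D15_WT_r3_0	0	.
chr1	72577	73575	peak0008_r3	0	.
chr1	120299	121321	peak0042_r3	0	.
chr1	181480	182509	peak0050_r3	0	.
chr2	3301	4276	peak0051_r3	0	.
chr2	47757	48746	peak0000_r3	0	.
chr2	67534	68518	peak0004_r3	0	.
chr2	72111	73111	noise_H3K27me3_D15_WT_r3_1	0	.
chr2	100397	101397	noise_H3K27me3_D15_WT_r3_2	0	.
chr2	117478	118472	peak0049_r3	0	.
chr2	123336	124336	noise_H3K27me3_D15_WT_r3_3	0	.
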