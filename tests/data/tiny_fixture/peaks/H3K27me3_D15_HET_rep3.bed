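chr1	20707	21695	peak0007_r3	0	.
chr1	39117	40117	noise_H3K27me3_D15_HET_r3_2	0	.
chr1	72573	73585	peak0008_r3	0	.
chr1	120292	121309	peak0042_r3	0	.
chr1	159812	160812	noise_H3K27me3_D15_HET_r3_1	0	.
chr2	3288	4305	peak0051_r3	0	.
chr2	47767	48747	peak0000_r3	0	.
chr2	67528	68534	peak0004_r3	0	.
chr2	117470	118483	peak0049_r3	0	.
chr2	126495	127495	noise_H3K27me3_D15_HET_r3_3	0	.
chr2	130591	131591	noise_H3K27me3_D15_HET_r3_0	0	.
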