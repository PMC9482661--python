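chr1	11558	12558	peak0022_r4	0	.
chr1	20699	21700	peak0007_r4	0	.
chr1	30372	31372	noise_H3K27me3_D35_HET_r4_1	0	.
chr1	32840	33840	noise_H3K27me3_D35_HET_r4_2	0	.
chr1	72580	73578	peak0008_r4	0	.
chr1	120301	121321	peak0042_r4	0	.
chr1	148824	149824	noise_H3K27me3_D35_HET_r4_3	0	.
chr1	181504	182488	peak0050_r4	0	.
chr2	3285	4307	peak0051_r4	0	.
chr2	47748	48758	peak0000_r4	0	.
chr2	67534	68529	peak0004_r4	0	.
chr2	117469	118482	peak0049_r4	0	.
chr2	135460	136460	noise_H3K27me3_D35_HET_r4_0	0	.
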