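chr1	11564	12557	peak0022_r1	0	.
chr1	20700	21700	peak0007_r1	0	.
chr1	72582	73573	peak0008_r1	0	.
chr1	86551	87551	noise_H3K27me3_D35_WT_r1_3	0	.
chr1	120314	121306	peak0042_r1	0	.
chr1	181491	182501	peak0050_r1	0	.
chr1	185591	186591	noise_H3K27me3_D35_WT_r1_1	0	.
chr2	3276	4307	peak0051_r1	0	.
chr2	10976	11976	noise_H3K27me3_D35_WT_r1_2	0	.
chr2	38603	39603	noise_H3K27me3_D35_WT_r1_0	0	.
chr2	47739	48746	peak0000_r1	0	.
chr2	67525	68510	peak0004_r1	0	.
chr2	117460	118480	peak0049_r1	0	.
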