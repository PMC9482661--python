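chr1	11556	12562	peak0022_r2	0	.
chr1	67549	68549	noise_H3K27me3_D35_WT_r2_0	0	.
chr1	72569	73590	peak0008_r2	0	.
chr1	120301	121307	peak0042_r2	0	.
chr1	181484	182487	peak0050_r2	0	.
chr2	3302	4296	peak0051_r2	0	.
chr2	47754	48743	peak0000_r2	0	.
chr2	67526	68523	peak0004_r2	0	.
chr2	78807	79807	noise_H3K27me3_D35_WT_r2_2	0	.
chr2	117465	118467	peak0049_r2	0	.
chr2	120477	121477	noise_H3K27me3_D35_WT_r2_1	0	.
chr2	146608	147608	noise_H3K27me3_D35_WT_r2_3	0	.
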