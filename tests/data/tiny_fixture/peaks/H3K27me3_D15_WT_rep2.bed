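chr1	20707	21689	peak0007_r2	0	.
chr1	51381	52381	noise_H3K27me3_D15_WT_r2_3	0	.
chr1	79988	80988	noise_H3K27me3_D15_WT_r2_0	0	.
chr1	120306	121286	peak0042_r2	0	.
chr1	170584	171584	noise_H3K27me3_D15_WT_r2_2	0	.
chr1	181486	182491	peak0050_r2	0	.
chr1	191214	192229	peak0029_r2	0	.
chr2	3293	4284	peak0051_r2	0	.
chr2	47742	48762	peak0000_r2	0	.
chr2	67538	68510	peak0004_r2	0	.
chr2	79672	80672	noise_H3K27me3_D15_WT_r2_1	0	.
chr2	117474	118477	peak0049_r2	0	.
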