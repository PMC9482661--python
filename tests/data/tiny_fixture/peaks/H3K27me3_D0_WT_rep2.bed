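chr1	20708	21703	peak0007_r2	0	.
chr1	77684	78679	peak0015_r2	0	.
chr1	83215	84215	noise_H3K27me3_D0_WT_r2_1	0	.
chr1	154425	155425	noise_H3K27me3_D0_WT_r2_3	0	.
chr1	181500	182498	peak0050_r2	0	.
chr1	189048	190048	noise_H3K27me3_D0_WT_r2_2	0	.
chr2	3300	4298	peak0051_r2	0	.
chr2	12322	13322	noise_H3K27me3_D0_WT_r2_0	0	.
chr2	47749	48752	peak0000_r2	0	.
chr2	67521	68538	peak0004_r2	0	.
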