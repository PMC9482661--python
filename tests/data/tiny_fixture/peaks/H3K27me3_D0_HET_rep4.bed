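chr1	20711	21703	peak0007_r4	0	.
chr1	77694	78694	peak0015_r4	0	.
chr1	172957	173957	noise_H3K27me3_D0_HET_r4_0	0	.
chr1	181497	182503	peak0050_r4	0	.
chr1	195641	196641	noise_H3K27me3_D0_HET_r4_2	0	.
chr2	3303	4297	peak0051_r4	0	.
chr2	47768	48762	peak0000_r4	0	.
chr2	50643	51643	noise_H3K27me3_D0_HET_r4_1	0	.
chr2	106786	107786	noise_H3K27me3_D0_HET_r4_3	0	.
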