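chr1	20695	21706	peak0007_r1	0	.
chr1	59123	60123	noise_H3K27me3_D15_HET_r1_1	0	.
chr1	72574	73556	peak0008_r1	0	.
chr1	82461	83461	noise_H3K27me3_D15_HET_r1_2	0	.
chr1	112557	113557	noise_H3K27me3_D15_HET_r1_0	0	.
chr1	120304	121277	peak0042_r1	0	.
chr1	181487	182501	peak0050_r1	0	.
chr1	191215	192220	peak0029_r1	0	.
chr2	117481	118476	peak0049_r1	0	.
chr2	137128	138128	noise_H3K27me3_D15_HET_r1_3	0	.
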