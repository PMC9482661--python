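chr1	18312	19312	noise_H3K27me3_D15_HET_r4_2	0	.
chr1	30145	31145	noise_H3K27me3_D15_HET_r4_1	0	.
chr1	123201	124201	noise_H3K27me3_D15_HET_r4_3	0	.
chr1	175940	176940	noise_H3K27me3_D15_HET_r4_0	0	.
chr1	181498	182506	peak0050_r4	0	.
chr1	191224	192220	peak0029_r4	0	.
chr2	3301	4302	peak0051_r4	0	.
chr2	47749	48755	peak0000_r4	0	.
chr2	117474	118496	peak0049_r4	0	.
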