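chr1	20717	21701	peak0007_r1	0	.
chr1	181486	182479	peak0050_r1	0	.
chr1	192970	193970	noise_H3K27me3_D0_HET_r1_2	0	.
chr2	47759	48732	peak0000_r1	0	.
chr2	50696	51696	noise_H3K27me3_D0_HET_r1_3	0	.
chr2	58175	59175	noise_H3K27me3_D0_HET_r1_1	0	.
chr2	78915	79915	noise_H3K27me3_D0_HET_r1_0	0	.
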