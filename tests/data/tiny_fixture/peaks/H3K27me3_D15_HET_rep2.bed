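chr1	20687	21709	peak0007_r2	0	.
chr1	63402	64402	noise_H3K27me3_D15_HET_r2_3	0	.
chr1	72586	73588	peak0008_r2	0	.
chr1	114625	115625	noise_H3K27me3_D15_HET_r2_1	0	.
chr1	120285	121324	peak0042_r2	0	.
chr1	181488	182482	peak0050_r2	0	.
chr1	188003	189003	noise_H3K27me3_D15_HET_r2_2	0	.
chr1	191213	192213	peak0029_r2	0	.
chr2	3290	4293	peak0051_r2	0	.
chr2	47757	48743	peak0000_r2	0	.
chr2	67516	68531	peak0004_r2	0	.
chr2	80235	81235	noise_H3K27me3_D15_HET_r2_0	0	.
chr2	117485	118473	peak0049_r2	0	.
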