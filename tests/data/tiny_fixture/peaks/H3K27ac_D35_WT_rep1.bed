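chr1	11765	12367	peak0022_r1	0	.
chr1	15891	16485	peak0035_r1	0	.
chr1	20913	21500	peak0007_r1	0	.
chr1	26693	27307	peak0046_r1	0	.
chr1	32983	33583	noise_H3K27ac_D35_WT_r1_0	0	.
chr1	36252	36849	peak0027_r1	0	.
chr1	45131	45717	peak0043_r1	0	.
chr1	49554	50152	peak0034_r1	0	.
chr1	55563	56170	peak0005_r1	0	.
chr1	61135	61737	peak0026_r1	0	.
chr1	72803	73369	peak0008_r1	0	.
chr1	94485	95115	peak0025_r1	0	.
chr1	99957	100558	peak0048_r1	0	.
chr1	103740	104334	peak0024_r1	0	.
chr1	108565	109175	peak0045_r1	0	.
chr1	111012	111599	peak0003_r1	0	.
chr1	156404	157004	noise_H3K27ac_D35_WT_r1_1	0	.
chr1	189426	190026	noise_H3K27ac_D35_WT_r1_3	0	.
chr2	18767	19374	peak0002_r1	0	.
chr2	27784	28370	peak0041_r1	0	.
chr2	41629	42227	peak0009_r1	0	.
chr2	43533	44125	peak0044_r1	0	.
chr2	47951	48551	peak0000_r1	0	.
chr2	67726	68321	peak0004_r1	0	.
chr2	72484	73084	noise_H3K27ac_D35_WT_r1_2	0	.
chr2	76225	76855	peak0001_r1	0	.
chr2	94454	95071	peak0006_r1	0	.
chr2	103240	103820	peak0037_r1	0	.
chr2	117688	118256	peak0049_r1	0	.
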