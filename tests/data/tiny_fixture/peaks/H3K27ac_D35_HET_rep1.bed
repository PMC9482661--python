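chr1	11757	12353	peak0022_r1	0	.
chr1	15906	16486	peak0035_r1	0	.
chr1	20901	21492	peak0007_r1	0	.
chr1	26686	27279	peak0046_r1	0	.
chr1	36247	36841	peak0027_r1	0	.
chr1	49542	50173	peak0034_r1	0	.
chr1	55559	56163	peak0005_r1	0	.
chr1	61164	61782	peak0026_r1	0	.
chr1	72786	73396	peak0008_r1	0	.
chr1	94487	95092	peak0025_r1	0	.
chr1	99956	100535	peak0048_r1	0	.
chr1	103732	104351	peak0024_r1	0	.
chr1	108576	109177	peak0045_r1	0	.
chr1	111008	111597	peak0003_r1	0	.
chr1	130418	131012	peak0038_r1	0	.
chr1	141331	141931	noise_H3K27ac_D35_HET_r1_1	0	.
chr2	3517	4092	peak0051_r1	0	.
chr2	26413	27013	noise_H3K27ac_D35_HET_r1_3	0	.
chr2	27774	28394	peak0041_r1	0	.
chr2	41638	42241	peak0009_r1	0	.
chr2	43537	44130	peak0044_r1	0	.
chr2	47947	48563	peak0000_r1	0	.
chr2	67722	68324	peak0004_r1	0	.
chr2	76234	76839	peak0001_r1	0	.
chr2	94469	95064	peak0006_r1	0	.
chr2	103243	103831	peak0037_r1	0	.
chr2	112765	113365	noise_H3K27ac_D35_HET_r1_2	0	.
chr2	117668	118281	peak0049_r1	0	.
chr2	141607	142207	noise_H3K27ac_D35_HET_r1_0	0	.
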