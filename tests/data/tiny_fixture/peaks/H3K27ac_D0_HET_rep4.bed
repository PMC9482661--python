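chr1	3559	4163	peak0032_r4	0	.
chr1	15899	16490	peak0035_r4	0	.
chr1	20894	21507	peak0007_r4	0	.
chr1	26690	27299	peak0046_r4	0	.
chr1	49541	50161	peak0034_r4	0	.
chr1	62608	63208	noise_H3K27ac_D0_HET_r4_2	0	.
chr1	72772	73360	peak0008_r4	0	.
chr1	77888	78483	peak0015_r4	0	.
chr1	81515	82115	noise_H3K27ac_D0_HET_r4_1	0	.
chr1	87948	88548	noise_H3K27ac_D0_HET_r4_0	0	.
chr1	99954	100556	peak0048_r4	0	.
chr1	110997	111600	peak0003_r4	0	.
chr1	130405	131004	peak0038_r4	0	.
chr1	132238	132833	peak0013_r4	0	.
chr1	143405	143972	peak0012_r4	0	.
chr1	191432	192033	peak0029_r4	0	.
chr2	18782	19366	peak0002_r4	0	.
chr2	41632	42220	peak0009_r4	0	.
chr2	47957	48568	peak0000_r4	0	.
chr2	67751	68339	peak0004_r4	0	.
chr2	76238	76831	peak0001_r4	0	.
chr2	88656	89233	peak0030_r4	0	.
chr2	96191	96790	peak0010_r4	0	.
chr2	99875	100475	noise_H3K27ac_D0_HET_r4_3	0	.
chr2	103256	103832	peak0037_r4	0	.
chr2	110650	111238	peak0028_r4	0	.
chr2	117657	118293	peak0049_r4	0	.
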