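chr1	3548	4155	peak0032_r2	0	.
chr1	10156	10756	noise_H3K27ac_D15_HET_r2_1	0	.
chr1	20907	21500	peak0007_r2	0	.
chr1	26696	27273	peak0046_r2	0	.
chr1	45107	45707	peak0043_r2	0	.
chr1	54459	55065	peak0020_r2	0	.
chr1	55569	56144	peak0005_r2	0	.
chr1	68874	69474	noise_H3K27ac_D15_HET_r2_2	0	.
chr1	72795	73383	peak0008_r2	0	.
chr1	99949	100550	peak0048_r2	0	.
chr1	108567	109163	peak0045_r2	0	.
chr1	110987	111591	peak0003_r2	0	.
chr1	162731	163334	peak0016_r2	0	.
chr1	186709	187309	noise_H3K27ac_D15_HET_r2_0	0	.
chr1	191414	192031	peak0029_r2	0	.
chr2	8058	8653	peak0019_r2	0	.
chr2	18783	19354	peak0002_r2	0	.
chr2	27770	28400	peak0041_r2	0	.
chr2	41628	42222	peak0009_r2	0	.
chr2	43521	44132	peak0044_r2	0	.
chr2	47970	48545	peak0000_r2	0	.
chr2	67705	68333	peak0004_r2	0	.
chr2	76264	76861	peak0001_r2	0	.
chr2	88655	89253	peak0030_r2	0	.
chr2	108764	109386	peak0017_r2	0	.
chr2	110624	111238	peak0028_r2	0	.
chr2	117691	118281	peak0049_r2	0	.
chr2	127594	128194	noise_H3K27ac_D15_HET_r2_3	0	.
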