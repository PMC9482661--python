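chr1	3540	4148	peak0032_r1	0	.
chr1	20912	21492	peak0007_r1	0	.
chr1	26689	27280	peak0046_r1	0	.
chr1	45110	45701	peak0043_r1	0	.
chr1	54447	55068	peak0020_r1	0	.
chr1	71406	71990	peak0031_r1	0	.
chr1	72772	73367	peak0008_r1	0	.
chr1	99947	100557	peak0048_r1	0	.
chr1	108577	109166	peak0045_r1	0	.
chr1	110997	111613	peak0003_r1	0	.
chr1	133962	134562	noise_H3K27ac_D15_HET_r1_2	0	.
chr1	158037	158637	noise_H3K27ac_D15_HET_r1_3	0	.
chr1	162724	163318	peak0016_r1	0	.
chr1	191424	192019	peak0029_r1	0	.
chr2	8061	8639	peak0019_r1	0	.
chr2	18773	19384	peak0002_r1	0	.
chr2	27773	28394	peak0041_r1	0	.
chr2	41661	42222	peak0009_r1	0	.
chr2	43547	44144	peak0044_r1	0	.
chr2	67731	68339	peak0004_r1	0	.
chr2	76241	76841	peak0001_r1	0	.
chr2	88664	89263	peak0030_r1	0	.
chr2	101369	101969	noise_H3K27ac_D15_HET_r1_1	0	.
chr2	106197	106797	noise_H3K27ac_D15_HET_r1_0	0	.
chr2	108784	109369	peak0017_r1	0	.
chr2	110618	111233	peak0028_r1	0	.
chr2	117677	118268	peak0049_r1	0	.
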