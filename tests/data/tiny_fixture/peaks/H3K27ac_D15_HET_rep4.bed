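chr1	3558	4164	peak0032_r4	0	.
chr1	20914	21502	peak0007_r4	0	.
chr1	26700	27321	peak0046_r4	0	.
chr1	54463	55071	peak0020_r4	0	.
chr1	55574	56152	peak0005_r4	0	.
chr1	71392	71983	peak0031_r4	0	.
chr1	72778	73389	peak0008_r4	0	.
chr1	83682	84282	noise_H3K27ac_D15_HET_r4_2	0	.
chr1	108593	109176	peak0045_r4	0	.
chr1	110994	111587	peak0003_r4	0	.
chr1	152016	152616	noise_H3K27ac_D15_HET_r4_1	0	.
chr1	162702	163327	peak0016_r4	0	.
chr1	191416	192021	peak0029_r4	0	.
chr2	6079	6679	noise_H3K27ac_D15_HET_r4_3	0	.
chr2	8041	8662	peak0019_r4	0	.
chr2	18786	19381	peak0002_r4	0	.
chr2	41621	42242	peak0009_r4	0	.
chr2	43534	44123	peak0044_r4	0	.
chr2	47952	48549	peak0000_r4	0	.
chr2	67729	68346	peak0004_r4	0	.
chr2	76242	76836	peak0001_r4	0	.
chr2	77561	78161	noise_H3K27ac_D15_HET_r4_0	0	.
chr2	88656	89259	peak0030_r4	0	.
chr2	108750	109352	peak0017_r4	0	.
chr2	110626	111246	peak0028_r4	0	.
chr2	117677	118271	peak0049_r4	0	.
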