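chr1	15900	16503	peak0035_r1	0	.
chr1	20902	21511	peak0007_r1	0	.
chr1	49551	50144	peak0034_r1	0	.
chr1	52626	53226	noise_H3K27ac_D0_HET_r1_1	0	.
chr1	71425	72011	peak0031_r1	0	.
chr1	72777	73373	peak0008_r1	0	.
chr1	77891	78482	peak0015_r1	0	.
chr1	99948	100543	peak0048_r1	0	.
chr1	111004	111601	peak0003_r1	0	.
chr1	130418	131009	peak0038_r1	0	.
chr1	132241	132823	peak0013_r1	0	.
chr1	143408	143975	peak0012_r1	0	.
chr1	191410	192018	peak0029_r1	0	.
chr2	18791	19379	peak0002_r1	0	.
chr2	41632	42242	peak0009_r1	0	.
chr2	45962	46562	noise_H3K27ac_D0_HET_r1_0	0	.
chr2	47947	48568	peak0000_r1	0	.
chr2	74294	74894	noise_H3K27ac_D0_HET_r1_3	0	.
chr2	76250	76838	peak0001_r1	0	.
chr2	96190	96779	peak0010_r1	0	.
chr2	103234	103840	peak0037_r1	0	.
chr2	110623	111219	peak0028_r1	0	.
chr2	117682	118284	peak0049_r1	0	.
chr2	147038	147638	noise_H3K27ac_D0_HET_r1_2	0	.
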