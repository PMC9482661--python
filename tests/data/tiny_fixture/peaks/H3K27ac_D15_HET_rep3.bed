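chr1	3547	4160	peak0032_r3	0	.
chr1	26709	27306	peak0046_r3	0	.
chr1	54458	55066	peak0020_r3	0	.
chr1	71399	71987	peak0031_r3	0	.
chr1	72793	73366	peak0008_r3	0	.
chr1	99954	100571	peak0048_r3	0	.
chr1	108577	109177	peak0045_r3	0	.
chr1	111020	111608	peak0003_r3	0	.
chr1	154279	154879	noise_H3K27ac_D15_HET_r3_2	0	.
chr1	162719	163322	peak0016_r3	0	.
chr1	191443	192020	peak0029_r3	0	.
chr2	8042	8651	peak0019_r3	0	.
chr2	18775	19388	peak0002_r3	0	.
chr2	27759	28370	peak0041_r3	0	.
chr2	41630	42237	peak0009_r3	0	.
chr2	43525	44125	peak0044_r3	0	.
chr2	47943	48544	peak0000_r3	0	.
chr2	57094	57694	noise_H3K27ac_D15_HET_r3_3	0	.
chr2	67739	68318	peak0004_r3	0	.
chr2	76250	76842	peak0001_r3	0	.
chr2	88640	89251	peak0030_r3	0	.
chr2	104918	105518	noise_H3K27ac_D15_HET_r3_0	0	.
chr2	108778	109371	peak0017_r3	0	.
chr2	110648	111223	peak0028_r3	0	.
chr2	117693	118297	peak0049_r3	0	.
chr2	145092	145692	noise_H3K27ac_D15_HET_r3_1	0	.
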