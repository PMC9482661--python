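chr1	3662	4071	peak0032_r2	0	.
chr1	21000	21411	peak0007_r2	0	.
chr1	26809	27200	peak0046_r2	0	.
chr1	54561	54975	peak0020_r2	0	.
chr1	55659	56079	peak0005_r2	0	.
chr1	71504	71916	peak0031_r2	0	.
chr1	72872	73275	peak0008_r2	0	.
chr1	124575	124975	noise_CHD2_D15_HET_r2_1	0	.
chr1	144836	145202	peak0018_r2	0	.
chr1	162808	163233	peak0016_r2	0	.
chr1	181811	182203	peak0050_r2	0	.
chr1	191524	191927	peak0029_r2	0	.
chr2	1706	2106	noise_CHD2_D15_HET_r2_3	0	.
chr2	8156	8568	peak0019_r2	0	.
chr2	14661	15054	peak0033_r2	0	.
chr2	18870	19267	peak0002_r2	0	.
chr2	20253	20645	peak0040_r2	0	.
chr2	27878	28288	peak0041_r2	0	.
chr2	30227	30613	peak0021_r2	0	.
chr2	41735	42134	peak0009_r2	0	.
chr2	43650	44043	peak0044_r2	0	.
chr2	48061	48447	peak0000_r2	0	.
chr2	52879	53305	peak0047_r2	0	.
chr2	56616	57016	noise_CHD2_D15_HET_r2_0	0	.
chr2	57928	58328	noise_CHD2_D15_HET_r2_2	0	.
chr2	67817	68241	peak0004_r2	0	.
chr2	76334	76748	peak0001_r2	0	.
chr2	88743	89160	peak0030_r2	0	.
chr2	108852	109262	peak0017_r2	0	.
chr2	110720	111133	peak0028_r2	0	.
chr2	117770	118172	peak0049_r2	0	.
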