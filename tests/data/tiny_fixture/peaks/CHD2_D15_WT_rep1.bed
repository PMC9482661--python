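chr1	3668	4055	peak0032_r1	0	.
chr1	8584	8984	noise_CHD2_D15_WT_r1_3	0	.
chr1	15096	15496	noise_CHD2_D15_WT_r1_0	0	.
chr1	26789	27202	peak0046_r1	0	.
chr1	45202	45597	peak0043_r1	0	.
chr1	54563	54974	peak0020_r1	0	.
chr1	71511	71895	peak0031_r1	0	.
chr1	72868	73291	peak0008_r1	0	.
chr1	100059	100479	peak0048_r1	0	.
chr1	108675	109047	peak0045_r1	0	.
chr1	111110	111495	peak0003_r1	0	.
chr1	144828	145218	peak0018_r1	0	.
chr1	162823	163214	peak0016_r1	0	.
chr1	181784	182182	peak0050_r1	0	.
chr1	191503	191904	peak0029_r1	0	.
chr2	3580	3989	peak0051_r1	0	.
chr2	8145	8553	peak0019_r1	0	.
chr2	9162	9562	noise_CHD2_D15_WT_r1_2	0	.
chr2	14646	15036	peak0033_r1	0	.
chr2	18885	19281	peak0002_r1	0	.
chr2	20248	20655	peak0040_r1	0	.
chr2	27876	28286	peak0041_r1	0	.
chr2	30209	30618	peak0021_r1	0	.
chr2	41732	42121	peak0009_r1	0	.
chr2	43650	44046	peak0044_r1	0	.
chr2	48053	48447	peak0000_r1	0	.
chr2	52883	53277	peak0047_r1	0	.
chr2	67841	68233	peak0004_r1	0	.
chr2	76354	76741	peak0001_r1	0	.
chr2	88760	89163	peak0030_r1	0	.
chr2	108879	109283	peak0017_r1	0	.
chr2	110738	111126	peak0028_r1	0	.
chr2	117782	118153	peak0049_r1	0	.
chr2	137033	137433	noise_CHD2_D15_WT_r1_1	0	.
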