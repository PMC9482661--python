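chr1	7759	8160	peak0023_r1	0	.
chr1	11853	12259	peak0022_r1	0	.
chr1	16003	16381	peak0035_r1	0	.
chr1	26805	27201	peak0046_r1	0	.
chr1	36344	36757	peak0027_r1	0	.
chr1	45214	45612	peak0043_r1	0	.
chr1	49660	50058	peak0034_r1	0	.
chr1	55662	56056	peak0005_r1	0	.
chr1	61253	61653	peak0026_r1	0	.
chr1	69392	69792	noise_CHD2_D35_WT_r1_2	0	.
chr1	72893	73281	peak0008_r1	0	.
chr1	94588	94985	peak0025_r1	0	.
chr1	100045	100468	peak0048_r1	0	.
chr1	103847	104228	peak0024_r1	0	.
chr1	108682	109068	peak0045_r1	0	.
chr1	111093	111501	peak0003_r1	0	.
chr1	120602	121004	peak0042_r1	0	.
chr1	125728	126148	peak0039_r1	0	.
chr1	130511	130906	peak0038_r1	0	.
chr1	171035	171435	noise_CHD2_D35_WT_r1_1	0	.
chr1	181796	182207	peak0050_r1	0	.
chr1	197683	198083	noise_CHD2_D35_WT_r1_0	0	.
chr2	3610	4000	peak0051_r1	0	.
chr2	18898	19276	peak0002_r1	0	.
chr2	20248	20657	peak0040_r1	0	.
chr2	27880	28271	peak0041_r1	0	.
chr2	34905	35305	noise_CHD2_D35_WT_r1_3	0	.
chr2	41735	42126	peak0009_r1	0	.
chr2	43636	44039	peak0044_r1	0	.
chr2	48053	48460	peak0000_r1	0	.
chr2	52894	53293	peak0047_r1	0	.
chr2	61400	61779	peak0036_r1	0	.
chr2	67811	68225	peak0004_r1	0	.
chr2	76338	76741	peak0001_r1	0	.
chr2	94570	94971	peak0006_r1	0	.
chr2	103357	103744	peak0037_r1	0	.
chr2	117788	118187	peak0049_r1	0	.
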