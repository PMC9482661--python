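chr1	3666	4062	peak0032_r4	0	.
chr1	21026	21414	peak0007_r4	0	.
chr1	26803	27193	peak0046_r4	0	.
chr1	54560	54964	peak0020_r4	0	.
chr1	71514	71888	peak0031_r4	0	.
chr1	72873	73287	peak0008_r4	0	.
chr1	100051	100438	peak0048_r4	0	.
chr1	108681	109086	peak0045_r4	0	.
chr1	111090	111502	peak0003_r4	0	.
chr1	116579	116979	noise_CHD2_D15_WT_r4_3	0	.
chr1	120615	121007	peak0042_r4	0	.
chr1	144824	145224	peak0018_r4	0	.
chr1	162819	163213	peak0016_r4	0	.
chr1	181794	182199	peak0050_r4	0	.
chr1	191532	191918	peak0029_r4	0	.
chr2	3599	3996	peak0051_r4	0	.
chr2	8143	8544	peak0019_r4	0	.
chr2	14663	15060	peak0033_r4	0	.
chr2	20239	20662	peak0040_r4	0	.
chr2	27886	28281	peak0041_r4	0	.
chr2	30226	30615	peak0021_r4	0	.
chr2	41730	42149	peak0009_r4	0	.
chr2	48059	48453	peak0000_r4	0	.
chr2	52902	53291	peak0047_r4	0	.
chr2	66804	67204	noise_CHD2_D15_WT_r4_1	0	.
chr2	67824	68226	peak0004_r4	0	.
chr2	76344	76756	peak0001_r4	0	.
chr2	88784	89168	peak0030_r4	0	.
chr2	89674	90074	noise_CHD2_D15_WT_r4_0	0	.
chr2	108882	109282	peak0017_r4	0	.
chr2	110732	111121	peak0028_r4	0	.
chr2	117779	118172	peak0049_r4	0	.
chr2	138966	139366	noise_CHD2_D15_WT_r4_2	0	.
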