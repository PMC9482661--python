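chr1	3509	4310	k4_g0000_r2	0	.
chr1	11664	12464	peak0022_r2	0	.
chr1	11799	12608	k4_g0002_r2	0	.
chr1	20817	21603	peak0007_r2	0	.
chr1	25056	25820	k4_g0005_r2	0	.
chr1	34222	35027	k4_g0007_r2	0	.
chr1	36007	36799	k4_g0008_r2	0	.
chr1	44908	45729	k4_g0009_r2	0	.
chr1	49344	50133	k4_g0010_r2	0	.
chr1	54281	55076	k4_g0011_r2	0	.
chr1	55394	56173	k4_g0012_r2	0	.
chr1	62380	63163	k4_g0014_r2	0	.
chr1	63544	64344	noise_H3K4me3_D35_HET_r2_3	0	.
chr1	71211	72021	k4_g0015_r2	0	.
chr1	72580	73366	k4_g0016_r2	0	.
chr1	72699	73482	peak0008_r2	0	.
chr1	77784	78551	k4_g0017_r2	0	.
chr1	86337	87137	noise_H3K4me3_D35_HET_r2_2	0	.
chr1	86734	87538	k4_g0018_r2	0	.
chr1	94472	95269	k4_g0020_r2	0	.
chr1	99759	100558	k4_g0021_r2	0	.
chr1	117941	118730	k4_g0025_r2	0	.
chr1	120395	121184	peak0042_r2	0	.
chr1	125645	126446	k4_g0027_r2	0	.
chr1	138221	139000	k4_g0030_r2	0	.
chr1	143171	143976	k4_g0031_r2	0	.
chr1	144757	145569	k4_g0032_r2	0	.
chr1	152352	153159	k4_g0033_r2	0	.
chr1	167995	168782	k4_g0037_r2	0	.
chr1	175306	176103	k4_g0038_r2	0	.
chr1	181513	182305	k4_g0039_r2	0	.
chr1	181586	182391	peak0050_r2	0	.
chr1	185966	186760	k4_g0040_r2	0	.
chr1	187876	188689	k4_g0041_r2	0	.
chr2	3385	4200	peak0051_r2	0	.
chr2	3439	4233	k4_g0043_r2	0	.
chr2	4905	5698	k4_g0044_r2	0	.
chr2	8014	8821	k4_g0045_r2	0	.
chr2	19998	20787	k4_g0048_r2	0	.
chr2	27762	28553	k4_g0049_r2	0	.
chr2	30029	30831	k4_g0050_r2	0	.
chr2	41529	42343	k4_g0052_r2	0	.
chr2	47847	48671	peak0000_r2	0	.
chr2	52656	53488	k4_g0055_r2	0	.
chr2	59557	60345	k4_g0056_r2	0	.
chr2	61271	62069	k4_g0057_r2	0	.
chr2	67632	68424	peak0004_r2	0	.
chr2	69514	70306	k4_g0059_r2	0	.
chr2	77096	77876	k4_g0061_r2	0	.
chr2	79839	80639	noise_H3K4me3_D35_HET_r2_1	0	.
chr2	88666	89458	k4_g0063_r2	0	.
chr2	94348	95150	k4_g0064_r2	0	.
chr2	103086	103874	k4_g0066_r2	0	.
chr2	108784	109584	k4_g0067_r2	0	.
chr2	110569	111381	k4_g0068_r2	0	.
chr2	117589	118383	peak0049_r2	0	.
chr2	120278	121078	noise_H3K4me3_D35_HET_r2_0	0	.
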