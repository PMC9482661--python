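chr1	3516	4310	k4_g0000_r4	0	.
chr1	11812	12602	k4_g0002_r4	0	.
chr1	15756	16542	k4_g0003_r4	0	.
chr1	20716	21499	k4_g0004_r4	0	.
chr1	20795	21595	peak0007_r4	0	.
chr1	26560	27383	k4_g0006_r4	0	.
chr1	34206	35028	k4_g0007_r4	0	.
chr1	40743	41543	noise_H3K4me3_D15_HET_r4_2	0	.
chr1	44921	45719	k4_g0009_r4	0	.
chr1	49341	50130	k4_g0010_r4	0	.
chr1	54285	55075	k4_g0011_r4	0	.
chr1	55398	56178	k4_g0012_r4	0	.
chr1	62362	63169	k4_g0014_r4	0	.
chr1	71201	72001	k4_g0015_r4	0	.
chr1	72600	73373	k4_g0016_r4	0	.
chr1	77779	78576	k4_g0017_r4	0	.
chr1	86740	87538	k4_g0018_r4	0	.
chr1	90055	90846	k4_g0019_r4	0	.
chr1	103795	104553	k4_g0022_r4	0	.
chr1	108603	109395	k4_g0023_r4	0	.
chr1	110960	111742	k4_g0024_r4	0	.
chr1	117934	118744	k4_g0025_r4	0	.
chr1	120408	121200	peak0042_r4	0	.
chr1	125674	126455	k4_g0027_r4	0	.
chr1	130449	131244	k4_g0028_r4	0	.
chr1	132033	132815	k4_g0029_r4	0	.
chr1	143161	143961	k4_g0031_r4	0	.
chr1	144767	145555	k4_g0032_r4	0	.
chr1	152357	153162	k4_g0033_r4	0	.
chr1	161166	161964	k4_g0035_r4	0	.
chr1	162703	163508	k4_g0036_r4	0	.
chr1	167993	168779	k4_g0037_r4	0	.
chr1	181506	182291	k4_g0039_r4	0	.
chr1	185948	186738	k4_g0040_r4	0	.
chr1	187892	188697	k4_g0041_r4	0	.
chr1	191225	192004	k4_g0042_r4	0	.
chr1	191335	192120	peak0029_r4	0	.
chr2	3379	4176	peak0051_r4	0	.
chr2	14408	15203	k4_g0046_r4	0	.
chr2	18635	19470	k4_g0047_r4	0	.
chr2	19986	20783	k4_g0048_r4	0	.
chr2	27756	28555	k4_g0049_r4	0	.
chr2	38138	38907	k4_g0051_r4	0	.
chr2	41514	42318	k4_g0052_r4	0	.
chr2	43411	44204	k4_g0053_r4	0	.
chr2	47844	48653	peak0000_r4	0	.
chr2	47886	48684	k4_g0054_r4	0	.
chr2	59548	60374	k4_g0056_r4	0	.
chr2	63346	64146	noise_H3K4me3_D15_HET_r4_1	0	.
chr2	67619	68424	peak0004_r4	0	.
chr2	67712	68507	k4_g0058_r4	0	.
chr2	69518	70298	k4_g0059_r4	0	.
chr2	70843	71643	noise_H3K4me3_D15_HET_r4_0	0	.
chr2	76054	76844	k4_g0060_r4	0	.
chr2	77109	77895	k4_g0061_r4	0	.
chr2	88685	89455	k4_g0063_r4	0	.
chr2	94328	95135	k4_g0064_r4	0	.
chr2	103068	103872	k4_g0066_r4	0	.
chr2	110552	111374	k4_g0068_r4	0	.
chr2	117557	118345	k4_g0069_r4	0	.
chr2	117586	118385	peak0049_r4	0	.
chr2	122538	123338	noise_H3K4me3_D15_HET_r4_3	0	.
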