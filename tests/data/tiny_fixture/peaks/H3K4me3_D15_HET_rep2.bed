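chr1	3521	4306	k4_g0000_r2	0	.
chr1	15749	16519	k4_g0003_r2	0	.
chr1	20707	21490	k4_g0004_r2	0	.
chr1	20803	21613	peak0007_r2	0	.
chr1	26547	27369	k4_g0006_r2	0	.
chr1	34219	35009	k4_g0007_r2	0	.
chr1	42403	43203	noise_H3K4me3_D15_HET_r2_0	0	.
chr1	44912	45707	k4_g0009_r2	0	.
chr1	49345	50145	k4_g0010_r2	0	.
chr1	54283	55069	k4_g0011_r2	0	.
chr1	55366	56223	k4_g0012_r2	0	.
chr1	62353	63174	k4_g0014_r2	0	.
chr1	71221	72006	k4_g0015_r2	0	.
chr1	72581	73383	k4_g0016_r2	0	.
chr1	72660	73486	peak0008_r2	0	.
chr1	77762	78574	k4_g0017_r2	0	.
chr1	86729	87556	k4_g0018_r2	0	.
chr1	90048	90834	k4_g0019_r2	0	.
chr1	99747	100567	k4_g0021_r2	0	.
chr1	103776	104561	k4_g0022_r2	0	.
chr1	106662	107462	noise_H3K4me3_D15_HET_r2_2	0	.
chr1	108599	109404	k4_g0023_r2	0	.
chr1	110939	111757	k4_g0024_r2	0	.
chr1	117953	118734	k4_g0025_r2	0	.
chr1	120391	121178	peak0042_r2	0	.
chr1	125646	126468	k4_g0027_r2	0	.
chr1	130436	131244	k4_g0028_r2	0	.
chr1	132016	132830	k4_g0029_r2	0	.
chr1	143137	143954	k4_g0031_r2	0	.
chr1	144769	145558	k4_g0032_r2	0	.
chr1	146742	147542	noise_H3K4me3_D15_HET_r2_3	0	.
chr1	152361	153155	k4_g0033_r2	0	.
chr1	161171	161955	k4_g0035_r2	0	.
chr1	162702	163493	k4_g0036_r2	0	.
chr1	167985	168780	k4_g0037_r2	0	.
chr1	181599	182407	peak0050_r2	0	.
chr1	185937	186770	k4_g0040_r2	0	.
chr1	187886	188689	k4_g0041_r2	0	.
chr1	191209	191998	k4_g0042_r2	0	.
chr1	191333	192130	peak0029_r2	0	.
chr2	3396	4192	peak0051_r2	0	.
chr2	14417	15197	k4_g0046_r2	0	.
chr2	18648	19444	k4_g0047_r2	0	.
chr2	20005	20783	k4_g0048_r2	0	.
chr2	27763	28558	k4_g0049_r2	0	.
chr2	38100	38910	k4_g0051_r2	0	.
chr2	41517	42314	k4_g0052_r2	0	.
chr2	43405	44207	k4_g0053_r2	0	.
chr2	47840	48654	peak0000_r2	0	.
chr2	47883	48669	k4_g0054_r2	0	.
chr2	59555	60378	k4_g0056_r2	0	.
chr2	67632	68435	peak0004_r2	0	.
chr2	67725	68509	k4_g0058_r2	0	.
chr2	69496	70291	k4_g0059_r2	0	.
chr2	76061	76865	k4_g0060_r2	0	.
chr2	77111	77906	k4_g0061_r2	0	.
chr2	88664	89477	k4_g0063_r2	0	.
chr2	94330	95142	k4_g0064_r2	0	.
chr2	103081	103874	k4_g0066_r2	0	.
chr2	117548	118350	k4_g0069_r2	0	.
chr2	117581	118374	peak0049_r2	0	.
chr2	130447	131247	noise_H3K4me3_D15_HET_r2_1	0	.
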