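chr1	3528	4324	k4_g0000_r1	0	.
chr1	11803	12605	k4_g0002_r1	0	.
chr1	15749	16536	k4_g0003_r1	0	.
chr1	20697	21500	k4_g0004_r1	0	.
chr1	26563	27356	k4_g0006_r1	0	.
chr1	44915	45683	k4_g0009_r1	0	.
chr1	49335	50136	k4_g0010_r1	0	.
chr1	54282	55081	k4_g0011_r1	0	.
chr1	55376	56201	k4_g0012_r1	0	.
chr1	71212	72015	k4_g0015_r1	0	.
chr1	72551	73388	k4_g0016_r1	0	.
chr1	72686	73479	peak0008_r1	0	.
chr1	77776	78567	k4_g0017_r1	0	.
chr1	86731	87532	k4_g0018_r1	0	.
chr1	99751	100557	k4_g0021_r1	0	.
chr1	103779	104574	k4_g0022_r1	0	.
chr1	108602	109401	k4_g0023_r1	0	.
chr1	110945	111753	k4_g0024_r1	0	.
chr1	117925	118745	k4_g0025_r1	0	.
chr1	120400	121202	peak0042_r1	0	.
chr1	125658	126442	k4_g0027_r1	0	.
chr1	130446	131242	k4_g0028_r1	0	.
chr1	132022	132840	k4_g0029_r1	0	.
chr1	143159	143975	k4_g0031_r1	0	.
chr1	144776	145550	k4_g0032_r1	0	.
chr1	152343	153149	k4_g0033_r1	0	.
chr1	152617	153417	noise_H3K4me3_D15_HET_r1_1	0	.
chr1	159742	160542	noise_H3K4me3_D15_HET_r1_3	0	.
chr1	161171	161991	k4_g0035_r1	0	.
chr1	162704	163494	k4_g0036_r1	0	.
chr1	167994	168800	k4_g0037_r1	0	.
chr1	173140	173940	noise_H3K4me3_D15_HET_r1_2	0	.
chr1	181511	182288	k4_g0039_r1	0	.
chr1	181601	182384	peak0050_r1	0	.
chr1	185947	186752	k4_g0040_r1	0	.
chr1	187889	188679	k4_g0041_r1	0	.
chr1	191225	192015	k4_g0042_r1	0	.
chr1	191328	192124	peak0029_r1	0	.
chr2	3389	4206	peak0051_r1	0	.
chr2	14419	15223	k4_g0046_r1	0	.
chr2	18640	19451	k4_g0047_r1	0	.
chr2	19996	20807	k4_g0048_r1	0	.
chr2	27754	28569	k4_g0049_r1	0	.
chr2	38134	38939	k4_g0051_r1	0	.
chr2	41520	42330	k4_g0052_r1	0	.
chr2	43412	44181	k4_g0053_r1	0	.
chr2	47854	48637	peak0000_r1	0	.
chr2	47904	48674	k4_g0054_r1	0	.
chr2	59553	60366	k4_g0056_r1	0	.
chr2	67612	68441	peak0004_r1	0	.
chr2	67739	68525	k4_g0058_r1	0	.
chr2	69503	70318	k4_g0059_r1	0	.
chr2	77093	77893	k4_g0061_r1	0	.
chr2	88671	89460	k4_g0063_r1	0	.
chr2	94332	95119	k4_g0064_r1	0	.
chr2	103082	103871	k4_g0066_r1	0	.
chr2	110558	111369	k4_g0068_r1	0	.
chr2	117548	118346	k4_g0069_r1	0	.
chr2	117586	118380	peak0049_r1	0	.
chr2	119825	120625	noise_H3K4me3_D15_HET_r1_0	0	.
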