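chr1	3522	4304	k4_g0000_r3	0	.
chr1	15739	16545	k4_g0003_r3	0	.
chr1	20671	21505	k4_g0004_r3	0	.
chr1	26569	27379	k4_g0006_r3	0	.
chr1	34226	35017	k4_g0007_r3	0	.
chr1	40833	41633	noise_H3K4me3_D15_HET_r3_2	0	.
chr1	44911	45706	k4_g0009_r3	0	.
chr1	49331	50142	k4_g0010_r3	0	.
chr1	55393	56171	k4_g0012_r3	0	.
chr1	62355	63159	k4_g0014_r3	0	.
chr1	71215	72024	k4_g0015_r3	0	.
chr1	72583	73384	k4_g0016_r3	0	.
chr1	77811	78577	k4_g0017_r3	0	.
chr1	86579	87379	noise_H3K4me3_D15_HET_r3_3	0	.
chr1	86736	87556	k4_g0018_r3	0	.
chr1	90055	90830	k4_g0019_r3	0	.
chr1	99778	100565	k4_g0021_r3	0	.
chr1	103780	104595	k4_g0022_r3	0	.
chr1	108610	109397	k4_g0023_r3	0	.
chr1	117946	118720	k4_g0025_r3	0	.
chr1	120415	121192	peak0042_r3	0	.
chr1	125636	126467	k4_g0027_r3	0	.
chr1	132026	132827	k4_g0029_r3	0	.
chr1	144756	145574	k4_g0032_r3	0	.
chr1	152371	153163	k4_g0033_r3	0	.
chr1	162706	163498	k4_g0036_r3	0	.
chr1	167989	168784	k4_g0037_r3	0	.
chr1	178095	178895	noise_H3K4me3_D15_HET_r3_1	0	.
chr1	181509	182295	k4_g0039_r3	0	.
chr1	181603	182380	peak0050_r3	0	.
chr1	185940	186780	k4_g0040_r3	0	.
chr1	187898	188679	k4_g0041_r3	0	.
chr1	191194	192007	k4_g0042_r3	0	.
chr1	191312	192116	peak0029_r3	0	.
chr2	3381	4192	peak0051_r3	0	.
chr2	14407	15202	k4_g0046_r3	0	.
chr2	18641	19450	k4_g0047_r3	0	.
chr2	20005	20810	k4_g0048_r3	0	.
chr2	27756	28551	k4_g0049_r3	0	.
chr2	38112	38926	k4_g0051_r3	0	.
chr2	43406	44207	k4_g0053_r3	0	.
chr2	47839	48665	peak0000_r3	0	.
chr2	59573	60378	k4_g0056_r3	0	.
chr2	67633	68436	peak0004_r3	0	.
chr2	67707	68515	k4_g0058_r3	0	.
chr2	69520	70309	k4_g0059_r3	0	.
chr2	76052	76877	k4_g0060_r3	0	.
chr2	77093	77881	k4_g0061_r3	0	.
chr2	88662	89464	k4_g0063_r3	0	.
chr2	94327	95138	k4_g0064_r3	0	.
chr2	103098	103870	k4_g0066_r3	0	.
chr2	110578	111368	k4_g0068_r3	0	.
chr2	112478	113278	noise_H3K4me3_D15_HET_r3_0	0	.
chr2	117558	118355	k4_g0069_r3	0	.
chr2	117562	118390	peak0049_r3	0	.
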