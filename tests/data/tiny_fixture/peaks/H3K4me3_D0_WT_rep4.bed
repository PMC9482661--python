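chr1	3519	4305	k4_g0000_r4	0	.
chr1	7465	8266	k4_g0001_r4	0	.
chr1	11795	12596	k4_g0002_r4	0	.
chr1	15735	16540	k4_g0003_r4	0	.
chr1	20693	21507	k4_g0004_r4	0	.
chr1	20811	21596	peak0007_r4	0	.
chr1	25034	25829	k4_g0005_r4	0	.
chr1	26577	27358	k4_g0006_r4	0	.
chr1	34213	35025	k4_g0007_r4	0	.
chr1	36009	36812	k4_g0008_r4	0	.
chr1	41702	42502	noise_H3K4me3_D0_WT_r4_0	0	.
chr1	44896	45717	k4_g0009_r4	0	.
chr1	54272	55064	k4_g0011_r4	0	.
chr1	55383	56177	k4_g0012_r4	0	.
chr1	57850	58650	noise_H3K4me3_D0_WT_r4_2	0	.
chr1	71230	72017	k4_g0015_r4	0	.
chr1	72573	73399	k4_g0016_r4	0	.
chr1	72698	73477	peak0008_r4	0	.
chr1	77755	78585	k4_g0017_r4	0	.
chr1	77807	78595	peak0015_r4	0	.
chr1	86748	87552	k4_g0018_r4	0	.
chr1	90047	90859	k4_g0019_r4	0	.
chr1	94460	95267	k4_g0020_r4	0	.
chr1	99750	100565	k4_g0021_r4	0	.
chr1	103766	104577	k4_g0022_r4	0	.
chr1	108602	109392	k4_g0023_r4	0	.
chr1	110949	111742	k4_g0024_r4	0	.
chr1	120299	121119	k4_g0026_r4	0	.
chr1	125677	126444	k4_g0027_r4	0	.
chr1	130447	131255	k4_g0028_r4	0	.
chr1	132018	132829	k4_g0029_r4	0	.
chr1	138222	139026	k4_g0030_r4	0	.
chr1	143163	143954	k4_g0031_r4	0	.
chr1	144785	145562	k4_g0032_r4	0	.
chr1	152366	153170	k4_g0033_r4	0	.
chr1	161167	161978	k4_g0035_r4	0	.
chr1	162699	163494	k4_g0036_r4	0	.
chr1	167981	168789	k4_g0037_r4	0	.
chr1	175307	176125	k4_g0038_r4	0	.
chr1	181514	182307	k4_g0039_r4	0	.
chr1	181584	182392	peak0050_r4	0	.
chr1	184894	185694	noise_H3K4me3_D0_WT_r4_3	0	.
chr1	185947	186757	k4_g0040_r4	0	.
chr1	187905	188714	k4_g0041_r4	0	.
chr1	191210	192010	k4_g0042_r4	0	.
chr1	191304	192124	peak0029_r4	0	.
chr2	4891	5691	k4_g0044_r4	0	.
chr2	8037	8817	k4_g0045_r4	0	.
chr2	14390	15203	k4_g0046_r4	0	.
chr2	18636	19460	k4_g0047_r4	0	.
chr2	20001	20794	k4_g0048_r4	0	.
chr2	27757	28544	k4_g0049_r4	0	.
chr2	30032	30823	k4_g0050_r4	0	.
chr2	41529	42325	k4_g0052_r4	0	.
chr2	43393	44207	k4_g0053_r4	0	.
chr2	47855	48651	peak0000_r4	0	.
chr2	47887	48681	k4_g0054_r4	0	.
chr2	52652	53472	k4_g0055_r4	0	.
chr2	57401	58201	noise_H3K4me3_D0_WT_r4_1	0	.
chr2	59537	60350	k4_g0056_r4	0	.
chr2	67634	68428	peak0004_r4	0	.
chr2	67730	68521	k4_g0058_r4	0	.
chr2	69497	70311	k4_g0059_r4	0	.
chr2	76052	76865	k4_g0060_r4	0	.
chr2	77109	77891	k4_g0061_r4	0	.
chr2	88675	89463	k4_g0063_r4	0	.
chr2	94332	95142	k4_g0064_r4	0	.
chr2	96086	96878	k4_g0065_r4	0	.
chr2	103081	103883	k4_g0066_r4	0	.
chr2	108780	109594	k4_g0067_r4	0	.
chr2	110576	111381	k4_g0068_r4	0	.
chr2	117554	118352	k4_g0069_r4	0	.
chr2	117589	118370	peak0049_r4	0	.
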