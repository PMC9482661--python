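chr1	11802	12603	k4_g0002_r3	0	.
chr1	15744	16565	k4_g0003_r3	0	.
chr1	20697	21497	k4_g0004_r3	0	.
chr1	20784	21606	peak0007_r3	0	.
chr1	24021	24821	noise_H3K4me3_D15_WT_r3_1	0	.
chr1	26577	27370	k4_g0006_r3	0	.
chr1	34217	35009	k4_g0007_r3	0	.
chr1	44927	45722	k4_g0009_r3	0	.
chr1	47948	48748	noise_H3K4me3_D15_WT_r3_3	0	.
chr1	49324	50127	k4_g0010_r3	0	.
chr1	54289	55078	k4_g0011_r3	0	.
chr1	55385	56175	k4_g0012_r3	0	.
chr1	62366	63169	k4_g0014_r3	0	.
chr1	71234	72009	k4_g0015_r3	0	.
chr1	72589	73366	k4_g0016_r3	0	.
chr1	72681	73489	peak0008_r3	0	.
chr1	77774	78562	k4_g0017_r3	0	.
chr1	86735	87539	k4_g0018_r3	0	.
chr1	89453	90253	noise_H3K4me3_D15_WT_r3_2	0	.
chr1	90055	90847	k4_g0019_r3	0	.
chr1	99752	100567	k4_g0021_r3	0	.
chr1	103777	104589	k4_g0022_r3	0	.
chr1	108592	109420	k4_g0023_r3	0	.
chr1	110943	111736	k4_g0024_r3	0	.
chr1	117924	118726	k4_g0025_r3	0	.
chr1	120395	121203	peak0042_r3	0	.
chr1	125652	126462	k4_g0027_r3	0	.
chr1	130463	131238	k4_g0028_r3	0	.
chr1	132038	132832	k4_g0029_r3	0	.
chr1	143156	143972	k4_g0031_r3	0	.
chr1	144758	145552	k4_g0032_r3	0	.
chr1	152338	153163	k4_g0033_r3	0	.
chr1	161173	161985	k4_g0035_r3	0	.
chr1	162713	163507	k4_g0036_r3	0	.
chr1	167977	168783	k4_g0037_r3	0	.
chr1	181498	182306	k4_g0039_r3	0	.
chr1	181597	182392	peak0050_r3	0	.
chr1	185956	186758	k4_g0040_r3	0	.
chr1	187882	188681	k4_g0041_r3	0	.
chr1	191212	192014	k4_g0042_r3	0	.
chr1	191317	192125	peak0029_r3	0	.
chr1	197866	198666	noise_H3K4me3_D15_WT_r3_0	0	.
chr2	3396	4199	peak0051_r3	0	.
chr2	18660	19443	k4_g0047_r3	0	.
chr2	20000	20788	k4_g0048_r3	0	.
chr2	27763	28547	k4_g0049_r3	0	.
chr2	38140	38927	k4_g0051_r3	0	.
chr2	41527	42316	k4_g0052_r3	0	.
chr2	43406	44202	k4_g0053_r3	0	.
chr2	47866	48646	peak0000_r3	0	.
chr2	47889	48670	k4_g0054_r3	0	.
chr2	59547	60353	k4_g0056_r3	0	.
chr2	67733	68519	k4_g0058_r3	0	.
chr2	69492	70310	k4_g0059_r3	0	.
chr2	76060	76869	k4_g0060_r3	0	.
chr2	77083	77901	k4_g0061_r3	0	.
chr2	88656	89470	k4_g0063_r3	0	.
chr2	94324	95135	k4_g0064_r3	0	.
chr2	103078	103871	k4_g0066_r3	0	.
chr2	117557	118341	k4_g0069_r3	0	.
chr2	117579	118388	peak0049_r3	0	.
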