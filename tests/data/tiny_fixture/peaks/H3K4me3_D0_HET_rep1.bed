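chr1	3519	4305	k4_g0000_r1	0	.
chr1	6070	6870	noise_H3K4me3_D0_HET_r1_3	0	.
chr1	7461	8252	k4_g0001_r1	0	.
chr1	11796	12604	k4_g0002_r1	0	.
chr1	15746	16531	k4_g0003_r1	0	.
chr1	18463	19263	noise_H3K4me3_D0_HET_r1_2	0	.
chr1	20694	21487	k4_g0004_r1	0	.
chr1	20797	21603	peak0007_r1	0	.
chr1	25060	25859	k4_g0005_r1	0	.
chr1	26572	27369	k4_g0006_r1	0	.
chr1	34217	35012	k4_g0007_r1	0	.
chr1	35998	36788	k4_g0008_r1	0	.
chr1	44911	45724	k4_g0009_r1	0	.
chr1	54265	55051	k4_g0011_r1	0	.
chr1	55374	56179	k4_g0012_r1	0	.
chr1	61120	61910	k4_g0013_r1	0	.
chr1	62356	63163	k4_g0014_r1	0	.
chr1	71212	72022	k4_g0015_r1	0	.
chr1	72589	73367	k4_g0016_r1	0	.
chr1	72687	73499	peak0008_r1	0	.
chr1	77781	78578	peak0015_r1	0	.
chr1	77791	78575	k4_g0017_r1	0	.
chr1	86733	87542	k4_g0018_r1	0	.
chr1	90061	90846	k4_g0019_r1	0	.
chr1	94466	95270	k4_g0020_r1	0	.
chr1	99776	100559	k4_g0021_r1	0	.
chr1	103777	104582	k4_g0022_r1	0	.
chr1	108598	109397	k4_g0023_r1	0	.
chr1	110949	111735	k4_g0024_r1	0	.
chr1	120318	121109	k4_g0026_r1	0	.
chr1	127238	128038	noise_H3K4me3_D0_HET_r1_1	0	.
chr1	143153	143957	k4_g0031_r1	0	.
chr1	144782	145544	k4_g0032_r1	0	.
chr1	147608	148408	noise_H3K4me3_D0_HET_r1_0	0	.
chr1	152351	153135	k4_g0033_r1	0	.
chr1	156813	157587	k4_g0034_r1	0	.
chr1	162697	163504	k4_g0036_r1	0	.
chr1	167968	168778	k4_g0037_r1	0	.
chr1	175299	176105	k4_g0038_r1	0	.
chr1	181506	182334	k4_g0039_r1	0	.
chr1	181594	182385	peak0050_r1	0	.
chr1	187895	188698	k4_g0041_r1	0	.
chr1	191227	192007	k4_g0042_r1	0	.
chr1	191322	192122	peak0029_r1	0	.
chr2	3399	4198	peak0051_r1	0	.
chr2	3434	4225	k4_g0043_r1	0	.
chr2	4889	5704	k4_g0044_r1	0	.
chr2	8015	8818	k4_g0045_r1	0	.
chr2	14408	15220	k4_g0046_r1	0	.
chr2	18648	19450	k4_g0047_r1	0	.
chr2	19973	20808	k4_g0048_r1	0	.
chr2	27769	28547	k4_g0049_r1	0	.
chr2	30043	30840	k4_g0050_r1	0	.
chr2	38144	38902	k4_g0051_r1	0	.
chr2	41516	42322	k4_g0052_r1	0	.
chr2	43399	44208	k4_g0053_r1	0	.
chr2	47859	48659	peak0000_r1	0	.
chr2	47888	48694	k4_g0054_r1	0	.
chr2	52652	53445	k4_g0055_r1	0	.
chr2	59546	60360	k4_g0056_r1	0	.
chr2	61267	62080	k4_g0057_r1	0	.
chr2	67638	68412	peak0004_r1	0	.
chr2	67722	68515	k4_g0058_r1	0	.
chr2	69510	70297	k4_g0059_r1	0	.
chr2	76072	76855	k4_g0060_r1	0	.
chr2	77091	77888	k4_g0061_r1	0	.
chr2	96077	96899	k4_g0065_r1	0	.
chr2	103085	103884	k4_g0066_r1	0	.
chr2	117556	118361	k4_g0069_r1	0	.
chr2	117587	118371	peak0049_r1	0	.
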