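chr1	3520	4312	k4_g0000_r3	0	.
chr1	7465	8267	k4_g0001_r3	0	.
chr1	11783	12593	k4_g0002_r3	0	.
chr1	20728	21481	k4_g0004_r3	0	.
chr1	20816	21605	peak0007_r3	0	.
chr1	25027	25842	k4_g0005_r3	0	.
chr1	26571	27379	k4_g0006_r3	0	.
chr1	30945	31745	noise_H3K4me3_D0_WT_r3_2	0	.
chr1	34230	35036	k4_g0007_r3	0	.
chr1	36008	36810	k4_g0008_r3	0	.
chr1	49335	50117	k4_g0010_r3	0	.
chr1	55354	56176	k4_g0012_r3	0	.
chr1	61095	61900	k4_g0013_r3	0	.
chr1	62378	63170	k4_g0014_r3	0	.
chr1	71209	71997	k4_g0015_r3	0	.
chr1	72569	73379	k4_g0016_r3	0	.
chr1	72683	73469	peak0008_r3	0	.
chr1	77753	78579	k4_g0017_r3	0	.
chr1	77800	78590	peak0015_r3	0	.
chr1	86756	87534	k4_g0018_r3	0	.
chr1	90053	90848	k4_g0019_r3	0	.
chr1	94462	95282	k4_g0020_r3	0	.
chr1	99759	100561	k4_g0021_r3	0	.
chr1	103771	104583	k4_g0022_r3	0	.
chr1	108590	109411	k4_g0023_r3	0	.
chr1	110940	111746	k4_g0024_r3	0	.
chr1	117936	118737	k4_g0025_r3	0	.
chr1	118789	119589	noise_H3K4me3_D0_WT_r3_0	0	.
chr1	120319	121109	k4_g0026_r3	0	.
chr1	125667	126467	k4_g0027_r3	0	.
chr1	130448	131242	k4_g0028_r3	0	.
chr1	132017	132814	k4_g0029_r3	0	.
chr1	138219	139022	k4_g0030_r3	0	.
chr1	143155	143954	k4_g0031_r3	0	.
chr1	144749	145565	k4_g0032_r3	0	.
chr1	152367	153166	k4_g0033_r3	0	.
chr1	156798	157603	k4_g0034_r3	0	.
chr1	161171	161971	k4_g0035_r3	0	.
chr1	162709	163511	k4_g0036_r3	0	.
chr1	167975	168794	k4_g0037_r3	0	.
chr1	175317	176095	k4_g0038_r3	0	.
chr1	181512	182294	k4_g0039_r3	0	.
chr1	181593	182409	peak0050_r3	0	.
chr1	185952	186766	k4_g0040_r3	0	.
chr1	187892	188692	k4_g0041_r3	0	.
chr1	191203	191989	k4_g0042_r3	0	.
chr1	191324	192124	peak0029_r3	0	.
chr1	192764	193564	noise_H3K4me3_D0_WT_r3_1	0	.
chr2	3411	4220	k4_g0043_r3	0	.
chr2	4889	5692	k4_g0044_r3	0	.
chr2	8018	8817	k4_g0045_r3	0	.
chr2	14418	15214	k4_g0046_r3	0	.
chr2	18648	19446	k4_g0047_r3	0	.
chr2	19990	20800	k4_g0048_r3	0	.
chr2	27757	28544	k4_g0049_r3	0	.
chr2	30046	30838	k4_g0050_r3	0	.
chr2	38133	38941	k4_g0051_r3	0	.
chr2	41529	42317	k4_g0052_r3	0	.
chr2	43403	44212	k4_g0053_r3	0	.
chr2	47864	48648	peak0000_r3	0	.
chr2	47885	48698	k4_g0054_r3	0	.
chr2	52664	53472	k4_g0055_r3	0	.
chr2	59561	60355	k4_g0056_r3	0	.
chr2	61276	62066	k4_g0057_r3	0	.
chr2	67628	68411	peak0004_r3	0	.
chr2	67720	68508	k4_g0058_r3	0	.
chr2	69495	70314	k4_g0059_r3	0	.
chr2	76042	76869	k4_g0060_r3	0	.
chr2	77078	77907	k4_g0061_r3	0	.
chr2	80649	81463	k4_g0062_r3	0	.
chr2	81333	82133	noise_H3K4me3_D0_WT_r3_3	0	.
chr2	88677	89473	k4_g0063_r3	0	.
chr2	94349	95133	k4_g0064_r3	0	.
chr2	96081	96879	k4_g0065_r3	0	.
chr2	103066	103883	k4_g0066_r3	0	.
chr2	108797	109594	k4_g0067_r3	0	.
chr2	110575	111371	k4_g0068_r3	0	.
chr2	117538	118337	k4_g0069_r3	0	.
chr2	117571	118382	peak0049_r3	0	.
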