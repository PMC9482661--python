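chr1	11650	12466	peak0022_r3	0	.
chr1	11798	12610	k4_g0002_r3	0	.
chr1	20697	21496	k4_g0004_r3	0	.
chr1	20794	21602	peak0007_r3	0	.
chr1	25037	25827	k4_g0005_r3	0	.
chr1	34230	35008	k4_g0007_r3	0	.
chr1	35981	36813	k4_g0008_r3	0	.
chr1	44926	45716	k4_g0009_r3	0	.
chr1	49333	50144	k4_g0010_r3	0	.
chr1	54281	55074	k4_g0011_r3	0	.
chr1	62365	63178	k4_g0014_r3	0	.
chr1	71229	72029	k4_g0015_r3	0	.
chr1	72587	73393	k4_g0016_r3	0	.
chr1	72688	73491	peak0008_r3	0	.
chr1	77778	78577	k4_g0017_r3	0	.
chr1	81612	82412	noise_H3K4me3_D35_WT_r3_1	0	.
chr1	86754	87558	k4_g0018_r3	0	.
chr1	94465	95259	k4_g0020_r3	0	.
chr1	99769	100559	k4_g0021_r3	0	.
chr1	117925	118725	k4_g0025_r3	0	.
chr1	120401	121198	peak0042_r3	0	.
chr1	125651	126443	k4_g0027_r3	0	.
chr1	138234	139018	k4_g0030_r3	0	.
chr1	143156	143972	k4_g0031_r3	0	.
chr1	144754	145555	k4_g0032_r3	0	.
chr1	152354	153152	k4_g0033_r3	0	.
chr1	167989	168782	k4_g0037_r3	0	.
chr1	175316	176106	k4_g0038_r3	0	.
chr1	184707	185507	noise_H3K4me3_D35_WT_r3_2	0	.
chr1	184924	185724	noise_H3K4me3_D35_WT_r3_3	0	.
chr1	185955	186763	k4_g0040_r3	0	.
chr1	187889	188700	k4_g0041_r3	0	.
chr2	3402	4195	peak0051_r3	0	.
chr2	3435	4220	k4_g0043_r3	0	.
chr2	4919	5698	k4_g0044_r3	0	.
chr2	8012	8833	k4_g0045_r3	0	.
chr2	20000	20792	k4_g0048_r3	0	.
chr2	27766	28540	k4_g0049_r3	0	.
chr2	30024	30831	k4_g0050_r3	0	.
chr2	38129	38910	k4_g0051_r3	0	.
chr2	41532	42330	k4_g0052_r3	0	.
chr2	43374	44204	k4_g0053_r3	0	.
chr2	45435	46235	noise_H3K4me3_D35_WT_r3_0	0	.
chr2	47849	48671	peak0000_r3	0	.
chr2	52686	53480	k4_g0055_r3	0	.
chr2	59567	60351	k4_g0056_r3	0	.
chr2	61284	62080	k4_g0057_r3	0	.
chr2	67635	68431	peak0004_r3	0	.
chr2	69500	70304	k4_g0059_r3	0	.
chr2	77095	77901	k4_g0061_r3	0	.
chr2	88659	89459	k4_g0063_r3	0	.
chr2	94332	95133	k4_g0064_r3	0	.
chr2	103093	103871	k4_g0066_r3	0	.
chr2	108769	109591	k4_g0067_r3	0	.
chr2	110549	111372	k4_g0068_r3	0	.
chr2	117581	118383	peak0049_r3	0	.
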