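chr1	3513	4310	k4_g0000_r1	0	.
chr1	11793	12604	k4_g0002_r1	0	.
chr1	20805	21599	peak0007_r1	0	.
chr1	25041	25830	k4_g0005_r1	0	.
chr1	35995	36811	k4_g0008_r1	0	.
chr1	43232	44032	noise_H3K4me3_D35_HET_r1_0	0	.
chr1	44920	45708	k4_g0009_r1	0	.
chr1	49343	50139	k4_g0010_r1	0	.
chr1	54279	55081	k4_g0011_r1	0	.
chr1	55375	56188	k4_g0012_r1	0	.
chr1	62345	63161	k4_g0014_r1	0	.
chr1	71221	72028	k4_g0015_r1	0	.
chr1	72584	73378	k4_g0016_r1	0	.
chr1	72689	73487	peak0008_r1	0	.
chr1	77776	78574	k4_g0017_r1	0	.
chr1	86735	87535	k4_g0018_r1	0	.
chr1	94481	95275	k4_g0020_r1	0	.
chr1	99759	100555	k4_g0021_r1	0	.
chr1	117940	118726	k4_g0025_r1	0	.
chr1	121870	122670	noise_H3K4me3_D35_HET_r1_1	0	.
chr1	125662	126454	k4_g0027_r1	0	.
chr1	138225	138993	k4_g0030_r1	0	.
chr1	143168	143973	k4_g0031_r1	0	.
chr1	144745	145556	k4_g0032_r1	0	.
chr1	152359	153165	k4_g0033_r1	0	.
chr1	167985	168774	k4_g0037_r1	0	.
chr1	177291	178091	noise_H3K4me3_D35_HET_r1_2	0	.
chr1	181502	182287	k4_g0039_r1	0	.
chr1	181586	182392	peak0050_r1	0	.
chr1	185944	186744	k4_g0040_r1	0	.
chr1	187878	188692	k4_g0041_r1	0	.
chr2	3397	4198	peak0051_r1	0	.
chr2	3428	4246	k4_g0043_r1	0	.
chr2	4889	5706	k4_g0044_r1	0	.
chr2	8027	8838	k4_g0045_r1	0	.
chr2	27737	28548	k4_g0049_r1	0	.
chr2	30023	30827	k4_g0050_r1	0	.
chr2	38128	38925	k4_g0051_r1	0	.
chr2	43410	44206	k4_g0053_r1	0	.
chr2	47860	48662	peak0000_r1	0	.
chr2	52662	53456	k4_g0055_r1	0	.
chr2	59550	60345	k4_g0056_r1	0	.
chr2	61295	62064	k4_g0057_r1	0	.
chr2	63416	64216	noise_H3K4me3_D35_HET_r1_3	0	.
chr2	67651	68432	peak0004_r1	0	.
chr2	69496	70318	k4_g0059_r1	0	.
chr2	77105	77886	k4_g0061_r1	0	.
chr2	88672	89467	k4_g0063_r1	0	.
chr2	94341	95138	k4_g0064_r1	0	.
chr2	103091	103886	k4_g0066_r1	0	.
chr2	108796	109574	k4_g0067_r1	0	.
chr2	110568	111371	k4_g0068_r1	0	.
chr2	117599	118383	peak0049_r1	0	.
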