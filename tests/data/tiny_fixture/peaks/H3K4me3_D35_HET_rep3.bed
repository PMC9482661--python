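chr1	3527	4315	k4_g0000_r3	0	.
chr1	11638	12481	peak0022_r3	0	.
chr1	11794	12587	k4_g0002_r3	0	.
chr1	20690	21499	k4_g0004_r3	0	.
chr1	25023	25843	k4_g0005_r3	0	.
chr1	34217	35032	k4_g0007_r3	0	.
chr1	35983	36795	k4_g0008_r3	0	.
chr1	49328	50131	k4_g0010_r3	0	.
chr1	54270	55077	k4_g0011_r3	0	.
chr1	55381	56189	k4_g0012_r3	0	.
chr1	62367	63184	k4_g0014_r3	0	.
chr1	71217	72028	k4_g0015_r3	0	.
chr1	72579	73375	k4_g0016_r3	0	.
chr1	72673	73473	peak0008_r3	0	.
chr1	77785	78574	k4_g0017_r3	0	.
chr1	86740	87542	k4_g0018_r3	0	.
chr1	90729	91529	noise_H3K4me3_D35_HET_r3_1	0	.
chr1	94464	95264	k4_g0020_r3	0	.
chr1	99770	100549	k4_g0021_r3	0	.
chr1	115666	116466	noise_H3K4me3_D35_HET_r3_0	0	.
chr1	117902	118729	k4_g0025_r3	0	.
chr1	125644	126459	k4_g0027_r3	0	.
chr1	138204	139020	k4_g0030_r3	0	.
chr1	143176	143950	k4_g0031_r3	0	.
chr1	144767	145564	k4_g0032_r3	0	.
chr1	156229	157029	noise_H3K4me3_D35_HET_r3_3	0	.
chr1	175315	176108	k4_g0038_r3	0	.
chr1	181584	182399	peak0050_r3	0	.
chr1	185953	186756	k4_g0040_r3	0	.
chr1	187891	188695	k4_g0041_r3	0	.
chr2	3415	4197	peak0051_r3	0	.
chr2	3447	4237	k4_g0043_r3	0	.
chr2	4875	5701	k4_g0044_r3	0	.
chr2	8018	8834	k4_g0045_r3	0	.
chr2	19999	20803	k4_g0048_r3	0	.
chr2	27748	28554	k4_g0049_r3	0	.
chr2	30040	30815	k4_g0050_r3	0	.
chr2	38129	38899	k4_g0051_r3	0	.
chr2	41536	42323	k4_g0052_r3	0	.
chr2	43383	44196	k4_g0053_r3	0	.
chr2	47847	48658	peak0000_r3	0	.
chr2	52667	53449	k4_g0055_r3	0	.
chr2	59565	60340	k4_g0056_r3	0	.
chr2	61273	62054	k4_g0057_r3	0	.
chr2	69516	70317	k4_g0059_r3	0	.
chr2	77092	77871	k4_g0061_r3	0	.
chr2	88653	89442	k4_g0063_r3	0	.
chr2	94354	95142	k4_g0064_r3	0	.
chr2	103067	103889	k4_g0066_r3	0	.
chr2	108790	109582	k4_g0067_r3	0	.
chr2	110569	111374	k4_g0068_r3	0	.
chr2	117583	118385	peak0049_r3	0	.
chr2	147261	148061	noise_H3K4me3_D35_HET_r3_2	0	.
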