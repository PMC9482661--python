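chr1	3501	4318	k4_g0000_r1	0	.
chr1	11640	12468	peak0022_r1	0	.
chr1	11796	12611	k4_g0002_r1	0	.
chr1	20680	21496	k4_g0004_r1	0	.
chr1	20798	21593	peak0007_r1	0	.
chr1	25033	25845	k4_g0005_r1	0	.
chr1	35994	36800	k4_g0008_r1	0	.
chr1	44907	45702	k4_g0009_r1	0	.
chr1	49315	50133	k4_g0010_r1	0	.
chr1	54284	55078	k4_g0011_r1	0	.
chr1	55384	56199	k4_g0012_r1	0	.
chr1	62380	63161	k4_g0014_r1	0	.
chr1	71205	72002	k4_g0015_r1	0	.
chr1	72573	73390	k4_g0016_r1	0	.
chr1	72687	73475	peak0008_r1	0	.
chr1	79743	80543	noise_H3K4me3_D35_WT_r1_3	0	.
chr1	86735	87536	k4_g0018_r1	0	.
chr1	94474	95252	k4_g0020_r1	0	.
chr1	99752	100550	k4_g0021_r1	0	.
chr1	117938	118724	k4_g0025_r1	0	.
chr1	125642	126449	k4_g0027_r1	0	.
chr1	138218	139035	k4_g0030_r1	0	.
chr1	143162	143957	k4_g0031_r1	0	.
chr1	152354	153160	k4_g0033_r1	0	.
chr1	167983	168789	k4_g0037_r1	0	.
chr1	175308	176103	k4_g0038_r1	0	.
chr1	181516	182288	k4_g0039_r1	0	.
chr1	181593	182390	peak0050_r1	0	.
chr1	185962	186770	k4_g0040_r1	0	.
chr1	187896	188682	k4_g0041_r1	0	.
chr2	3406	4200	peak0051_r1	0	.
chr2	3433	4223	k4_g0043_r1	0	.
chr2	4886	5696	k4_g0044_r1	0	.
chr2	8020	8817	k4_g0045_r1	0	.
chr2	19992	20788	k4_g0048_r1	0	.
chr2	30030	30840	k4_g0050_r1	0	.
chr2	38114	38915	k4_g0051_r1	0	.
chr2	41512	42326	k4_g0052_r1	0	.
chr2	43388	44194	k4_g0053_r1	0	.
chr2	47852	48655	peak0000_r1	0	.
chr2	49529	50329	noise_H3K4me3_D35_WT_r1_2	0	.
chr2	52672	53478	k4_g0055_r1	0	.
chr2	59547	60338	k4_g0056_r1	0	.
chr2	61276	62048	k4_g0057_r1	0	.
chr2	67614	68431	peak0004_r1	0	.
chr2	69501	70306	k4_g0059_r1	0	.
chr2	77097	77890	k4_g0061_r1	0	.
chr2	88660	89491	k4_g0063_r1	0	.
chr2	94347	95137	k4_g0064_r1	0	.
chr2	103082	103881	k4_g0066_r1	0	.
chr2	110558	111376	k4_g0068_r1	0	.
chr2	117584	118367	peak0049_r1	0	.
chr2	137729	138529	noise_H3K4me3_D35_WT_r1_1	0	.
chr2	137788	138588	noise_H3K4me3_D35_WT_r1_0	0	.
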