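chr1	11647	12447	peak0022_r2	0	.
chr1	11805	12603	k4_g0002_r2	0	.
chr1	18725	19525	noise_H3K4me3_D35_WT_r2_3	0	.
chr1	20702	21494	k4_g0004_r2	0	.
chr1	20795	21616	peak0007_r2	0	.
chr1	25032	25854	k4_g0005_r2	0	.
chr1	34230	35035	k4_g0007_r2	0	.
chr1	36002	36803	k4_g0008_r2	0	.
chr1	44911	45722	k4_g0009_r2	0	.
chr1	49320	50132	k4_g0010_r2	0	.
chr1	54270	55077	k4_g0011_r2	0	.
chr1	55381	56196	k4_g0012_r2	0	.
chr1	71198	72032	k4_g0015_r2	0	.
chr1	72572	73368	k4_g0016_r2	0	.
chr1	77777	78592	k4_g0017_r2	0	.
chr1	86744	87564	k4_g0018_r2	0	.
chr1	94492	95281	k4_g0020_r2	0	.
chr1	99741	100550	k4_g0021_r2	0	.
chr1	117932	118741	k4_g0025_r2	0	.
chr1	120414	121212	peak0042_r2	0	.
chr1	125651	126449	k4_g0027_r2	0	.
chr1	138219	139028	k4_g0030_r2	0	.
chr1	144759	145562	k4_g0032_r2	0	.
chr1	153643	154443	noise_H3K4me3_D35_WT_r2_2	0	.
chr1	167979	168786	k4_g0037_r2	0	.
chr1	175312	176103	k4_g0038_r2	0	.
chr1	181505	182307	k4_g0039_r2	0	.
chr1	181590	182398	peak0050_r2	0	.
chr1	185975	186756	k4_g0040_r2	0	.
chr1	187885	188676	k4_g0041_r2	0	.
chr2	3402	4189	peak0051_r2	0	.
chr2	3438	4228	k4_g0043_r2	0	.
chr2	4902	5683	k4_g0044_r2	0	.
chr2	8032	8838	k4_g0045_r2	0	.
chr2	19994	20798	k4_g0048_r2	0	.
chr2	27756	28552	k4_g0049_r2	0	.
chr2	38120	38932	k4_g0051_r2	0	.
chr2	41517	42327	k4_g0052_r2	0	.
chr2	43400	44198	k4_g0053_r2	0	.
chr2	47851	48631	peak0000_r2	0	.
chr2	52682	53462	k4_g0055_r2	0	.
chr2	59570	60367	k4_g0056_r2	0	.
chr2	61269	62079	k4_g0057_r2	0	.
chr2	67635	68436	peak0004_r2	0	.
chr2	94346	95121	k4_g0064_r2	0	.
chr2	103081	103876	k4_g0066_r2	0	.
chr2	108788	109587	k4_g0067_r2	0	.
chr2	117563	118386	peak0049_r2	0	.
chr2	128065	128865	noise_H3K4me3_D35_WT_r2_1	0	.
chr2	142216	143016	noise_H3K4me3_D35_WT_r2_0	0	.
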