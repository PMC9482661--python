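chr1	3639	4068	peak0032_r1	0	.
chr1	15987	16418	peak0035_r1	0	.
chr1	17419	17819	noise_CHD2_D0_HET_r1_3	0	.
chr1	21020	21407	peak0007_r1	0	.
chr1	26802	27190	peak0046_r1	0	.
chr1	49640	50059	peak0034_r1	0	.
chr1	71512	71897	peak0031_r1	0	.
chr1	72888	73273	peak0008_r1	0	.
chr1	77993	78387	peak0015_r1	0	.
chr1	100079	100453	peak0048_r1	0	.
chr1	111095	111515	peak0003_r1	0	.
chr1	116782	117182	noise_CHD2_D0_HET_r1_0	0	.
chr1	132332	132748	peak0013_r1	0	.
chr1	138390	138799	peak0011_r1	0	.
chr1	143481	143891	peak0012_r1	0	.
chr1	160449	160849	noise_CHD2_D0_HET_r1_2	0	.
chr1	168234	168616	peak0014_r1	0	.
chr1	181784	182178	peak0050_r1	0	.
chr1	191513	191923	peak0029_r1	0	.
chr2	3603	3989	peak0051_r1	0	.
chr2	14665	15055	peak0033_r1	0	.
chr2	18862	19252	peak0002_r1	0	.
chr2	41728	42143	peak0009_r1	0	.
chr2	48045	48458	peak0000_r1	0	.
chr2	61374	61792	peak0036_r1	0	.
chr2	67840	68231	peak0004_r1	0	.
chr2	76356	76742	peak0001_r1	0	.
chr2	80694	81094	noise_CHD2_D0_HET_r1_1	0	.
chr2	88746	89157	peak0030_r1	0	.
chr2	96279	96682	peak0010_r1	0	.
chr2	103347	103730	peak0037_r1	0	.
chr2	110722	111141	peak0028_r1	0	.
chr2	117769	118167	peak0049_r1	0	.
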