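chr1	1293	1693	noise_CHD2_D35_HET_r2_2	0	.
chr1	7757	8141	peak0023_r2	0	.
chr1	15980	16397	peak0035_r2	0	.
chr1	20998	21392	peak0007_r2	0	.
chr1	26800	27201	peak0046_r2	0	.
chr1	36348	36737	peak0027_r2	0	.
chr1	45202	45627	peak0043_r2	0	.
chr1	49670	50055	peak0034_r2	0	.
chr1	55663	56075	peak0005_r2	0	.
chr1	61259	61652	peak0026_r2	0	.
chr1	67964	68364	noise_CHD2_D35_HET_r2_1	0	.
chr1	72863	73305	peak0008_r2	0	.
chr1	94610	94999	peak0025_r2	0	.
chr1	100050	100444	peak0048_r2	0	.
chr1	103846	104221	peak0024_r2	0	.
chr1	108682	109073	peak0045_r2	0	.
chr1	111111	111494	peak0003_r2	0	.
chr1	120605	121002	peak0042_r2	0	.
chr1	125745	126135	peak0039_r2	0	.
chr1	130516	130902	peak0038_r2	0	.
chr1	181810	182187	peak0050_r2	0	.
chr2	3606	3988	peak0051_r2	0	.
chr2	18890	19268	peak0002_r2	0	.
chr2	20258	20632	peak0040_r2	0	.
chr2	27873	28279	peak0041_r2	0	.
chr2	41754	42147	peak0009_r2	0	.
chr2	43634	44024	peak0044_r2	0	.
chr2	48048	48470	peak0000_r2	0	.
chr2	52885	53294	peak0047_r2	0	.
chr2	61403	61787	peak0036_r2	0	.
chr2	67829	68231	peak0004_r2	0	.
chr2	69459	69859	noise_CHD2_D35_HET_r2_0	0	.
chr2	76342	76745	peak0001_r2	0	.
chr2	97556	97956	noise_CHD2_D35_HET_r2_3	0	.
chr2	103344	103750	peak0037_r2	0	.
chr2	117797	118167	peak0049_r2	0	.
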