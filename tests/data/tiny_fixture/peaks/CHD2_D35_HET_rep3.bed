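chr1	7751	8160	peak0023_r3	0	.
chr1	20994	21397	peak0007_r3	0	.
chr1	26798	27208	peak0046_r3	0	.
chr1	34586	34986	noise_CHD2_D35_HET_r3_2	0	.
chr1	36348	36754	peak0027_r3	0	.
chr1	45204	45598	peak0043_r3	0	.
chr1	49666	50055	peak0034_r3	0	.
chr1	55665	56076	peak0005_r3	0	.
chr1	61247	61650	peak0026_r3	0	.
chr1	72878	73275	peak0008_r3	0	.
chr1	94588	94993	peak0025_r3	0	.
chr1	100041	100428	peak0048_r3	0	.
chr1	103839	104244	peak0024_r3	0	.
chr1	108675	109085	peak0045_r3	0	.
chr1	120587	120990	peak0042_r3	0	.
chr1	125728	126139	peak0039_r3	0	.
chr1	130507	130902	peak0038_r3	0	.
chr1	137526	137926	noise_CHD2_D35_HET_r3_0	0	.
chr2	3601	4011	peak0051_r3	0	.
chr2	18878	19258	peak0002_r3	0	.
chr2	20249	20646	peak0040_r3	0	.
chr2	27890	28263	peak0041_r3	0	.
chr2	41721	42157	peak0009_r3	0	.
chr2	48043	48440	peak0000_r3	0	.
chr2	52890	53309	peak0047_r3	0	.
chr2	61382	61794	peak0036_r3	0	.
chr2	67835	68228	peak0004_r3	0	.
chr2	76329	76745	peak0001_r3	0	.
chr2	81253	81653	noise_CHD2_D35_HET_r3_1	0	.
chr2	94568	94946	peak0006_r3	0	.
chr2	102081	102481	noise_CHD2_D35_HET_r3_3	0	.
chr2	103322	103735	peak0037_r3	0	.
chr2	117790	118182	peak0049_r3	0	.
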