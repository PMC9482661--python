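chr1	11750	12343	peak0022_r4	0	.
chr1	15892	16510	peak0035_r4	0	.
chr1	19586	20186	noise_H3K27ac_D35_WT_r4_2	0	.
chr1	20909	21492	peak0007_r4	0	.
chr1	26698	27293	peak0046_r4	0	.
chr1	36236	36835	peak0027_r4	0	.
chr1	45082	45705	peak0043_r4	0	.
chr1	49548	50155	peak0034_r4	0	.
chr1	55563	56158	peak0005_r4	0	.
chr1	61160	61748	peak0026_r4	0	.
chr1	72775	73364	peak0008_r4	0	.
chr1	94498	95094	peak0025_r4	0	.
chr1	99958	100544	peak0048_r4	0	.
chr1	103752	104327	peak0024_r4	0	.
chr1	108585	109162	peak0045_r4	0	.
chr1	130420	131026	peak0038_r4	0	.
chr1	198005	198605	noise_H3K27ac_D35_WT_r4_3	0	.
chr2	3501	4116	peak0051_r4	0	.
chr2	17243	17843	noise_H3K27ac_D35_WT_r4_1	0	.
chr2	18769	19377	peak0002_r4	0	.
chr2	27774	28388	peak0041_r4	0	.
chr2	41647	42238	peak0009_r4	0	.
chr2	43524	44136	peak0044_r4	0	.
chr2	47964	48563	peak0000_r4	0	.
chr2	67724	68316	peak0004_r4	0	.
chr2	94451	95074	peak0006_r4	0	.
chr2	103257	103845	peak0037_r4	0	.
chr2	107321	107921	noise_H3K27ac_D35_WT_r4_0	0	.
chr2	117663	118268	peak0049_r4	0	.
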