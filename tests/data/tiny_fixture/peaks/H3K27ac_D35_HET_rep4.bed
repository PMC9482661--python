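chr1	15893	16493	peak0035_r4	0	.
chr1	20903	21494	peak0007_r4	0	.
chr1	26704	27317	peak0046_r4	0	.
chr1	28961	29561	noise_H3K27ac_D35_HET_r4_3	0	.
chr1	49548	50157	peak0034_r4	0	.
chr1	55562	56178	peak0005_r4	0	.
chr1	61131	61746	peak0026_r4	0	.
chr1	72759	73372	peak0008_r4	0	.
chr1	94478	95105	peak0025_r4	0	.
chr1	99933	100554	peak0048_r4	0	.
chr1	103748	104319	peak0024_r4	0	.
chr1	108561	109165	peak0045_r4	0	.
chr1	111007	111609	peak0003_r4	0	.
chr1	130399	130997	peak0038_r4	0	.
chr1	151121	151721	noise_H3K27ac_D35_HET_r4_1	0	.
chr1	188065	188665	noise_H3K27ac_D35_HET_r4_2	0	.
chr1	198922	199522	noise_H3K27ac_D35_HET_r4_0	0	.
chr2	3481	4096	peak0051_r4	0	.
chr2	18790	19367	peak0002_r4	0	.
chr2	27772	28394	peak0041_r4	0	.
chr2	41643	42236	peak0009_r4	0	.
chr2	43520	44127	peak0044_r4	0	.
chr2	47957	48537	peak0000_r4	0	.
chr2	67720	68326	peak0004_r4	0	.
chr2	76238	76831	peak0001_r4	0	.
chr2	94462	95089	peak0006_r4	0	.
chr2	103232	103840	peak0037_r4	0	.
chr2	117682	118287	peak0049_r4	0	.
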