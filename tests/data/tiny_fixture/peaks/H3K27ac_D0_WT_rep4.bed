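chr1	3564	4165	peak0032_r4	0	.
chr1	15903	16498	peak0035_r4	0	.
chr1	20904	21497	peak0007_r4	0	.
chr1	26692	27293	peak0046_r4	0	.
chr1	71419	71977	peak0031_r4	0	.
chr1	72795	73362	peak0008_r4	0	.
chr1	77912	78506	peak0015_r4	0	.
chr1	99945	100547	peak0048_r4	0	.
chr1	111015	111609	peak0003_r4	0	.
chr1	130423	131020	peak0038_r4	0	.
chr1	132243	132840	peak0013_r4	0	.
chr1	133751	134351	noise_H3K27ac_D0_WT_r4_2	0	.
chr1	143407	143995	peak0012_r4	0	.
chr1	152981	153581	noise_H3K27ac_D0_WT_r4_0	0	.
chr2	18780	19382	peak0002_r4	0	.
chr2	32530	33130	noise_H3K27ac_D0_WT_r4_1	0	.
chr2	47975	48556	peak0000_r4	0	.
chr2	54173	54773	noise_H3K27ac_D0_WT_r4_3	0	.
chr2	67726	68330	peak0004_r4	0	.
chr2	88650	89256	peak0030_r4	0	.
chr2	96194	96792	peak0010_r4	0	.
chr2	103237	103831	peak0037_r4	0	.
chr2	110654	111228	peak0028_r4	0	.
chr2	117673	118300	peak0049_r4	0	.
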