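chr1	3575	4162	peak0032_r3	0	.
chr1	15894	16500	peak0035_r3	0	.
chr1	20904	21500	peak0007_r3	0	.
chr1	26694	27314	peak0046_r3	0	.
chr1	49568	50143	peak0034_r3	0	.
chr1	71415	71994	peak0031_r3	0	.
chr1	72767	73369	peak0008_r3	0	.
chr1	77896	78487	peak0015_r3	0	.
chr1	99944	100554	peak0048_r3	0	.
chr1	111007	111589	peak0003_r3	0	.
chr1	130408	131029	peak0038_r3	0	.
chr1	132235	132837	peak0013_r3	0	.
chr1	143408	143994	peak0012_r3	0	.
chr1	191414	192011	peak0029_r3	0	.
chr1	195071	195671	noise_H3K27ac_D0_WT_r3_2	0	.
chr2	18768	19381	peak0002_r3	0	.
chr2	41636	42221	peak0009_r3	0	.
chr2	47957	48568	peak0000_r3	0	.
chr2	49688	50288	noise_H3K27ac_D0_WT_r3_1	0	.
chr2	76259	76839	peak0001_r3	0	.
chr2	88671	89257	peak0030_r3	0	.
chr2	91929	92529	noise_H3K27ac_D0_WT_r3_3	0	.
chr2	103232	103843	peak0037_r3	0	.
chr2	110639	111225	peak0028_r3	0	.
chr2	117690	118273	peak0049_r3	0	.
chr2	138122	138722	noise_H3K27ac_D0_WT_r3_0	0	.
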