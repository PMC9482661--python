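chr1	3561	4149	peak0032_r2	0	.
chr1	9322	9922	noise_H3K27ac_D0_HET_r2_2	0	.
chr1	15890	16500	peak0035_r2	0	.
chr1	26714	27296	peak0046_r2	0	.
chr1	49533	50139	peak0034_r2	0	.
chr1	71404	71992	peak0031_r2	0	.
chr1	72779	73367	peak0008_r2	0	.
chr1	77873	78484	peak0015_r2	0	.
chr1	91798	92398	noise_H3K27ac_D0_HET_r2_0	0	.
chr1	99965	100551	peak0048_r2	0	.
chr1	130433	131010	peak0038_r2	0	.
chr1	132227	132851	peak0013_r2	0	.
chr1	143389	144013	peak0012_r2	0	.
chr1	191429	192016	peak0029_r2	0	.
chr2	18781	19379	peak0002_r2	0	.
chr2	41643	42240	peak0009_r2	0	.
chr2	47952	48563	peak0000_r2	0	.
chr2	67730	68334	peak0004_r2	0	.
chr2	76249	76833	peak0001_r2	0	.
chr2	88644	89271	peak0030_r2	0	.
chr2	96186	96804	peak0010_r2	0	.
chr2	103237	103843	peak0037_r2	0	.
chr2	110646	111229	peak0028_r2	0	.
chr2	112707	113307	noise_H3K27ac_D0_HET_r2_3	0	.
chr2	117683	118294	peak0049_r2	0	.
chr2	145537	146137	noise_H3K27ac_D0_HET_r2_1	0	.
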