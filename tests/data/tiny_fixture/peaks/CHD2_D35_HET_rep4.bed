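chr1	7755	8154	peak0023_r4	0	.
chr1	11848	12249	peak0022_r4	0	.
chr1	15999	16395	peak0035_r4	0	.
chr1	20999	21400	peak0007_r4	0	.
chr1	26808	27194	peak0046_r4	0	.
chr1	36332	36753	peak0027_r4	0	.
chr1	45197	45610	peak0043_r4	0	.
chr1	49647	50060	peak0034_r4	0	.
chr1	52420	52820	noise_CHD2_D35_HET_r4_2	0	.
chr1	55660	56074	peak0005_r4	0	.
chr1	61238	61642	peak0026_r4	0	.
chr1	100053	100434	peak0048_r4	0	.
chr1	102796	103196	noise_CHD2_D35_HET_r4_0	0	.
chr1	103846	104232	peak0024_r4	0	.
chr1	108683	109078	peak0045_r4	0	.
chr1	111111	111476	peak0003_r4	0	.
chr1	120595	120998	peak0042_r4	0	.
chr1	125707	126144	peak0039_r4	0	.
chr1	130521	130924	peak0038_r4	0	.
chr1	181776	182199	peak0050_r4	0	.
chr2	3594	4000	peak0051_r4	0	.
chr2	18873	19258	peak0002_r4	0	.
chr2	20227	20653	peak0040_r4	0	.
chr2	27885	28279	peak0041_r4	0	.
chr2	41737	42141	peak0009_r4	0	.
chr2	43641	44040	peak0044_r4	0	.
chr2	48037	48461	peak0000_r4	0	.
chr2	61415	61774	peak0036_r4	0	.
chr2	67813	68222	peak0004_r4	0	.
chr2	76333	76742	peak0001_r4	0	.
chr2	94565	94960	peak0006_r4	0	.
chr2	98447	98847	noise_CHD2_D35_HET_r4_1	0	.
chr2	103346	103742	peak0037_r4	0	.
chr2	131800	132200	noise_CHD2_D35_HET_r4_3	0	.
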