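chr1	3554	4150	peak0032_r3	0	.
chr1	15881	16496	peak0035_r3	0	.
chr1	20894	21500	peak0007_r3	0	.
chr1	26696	27314	peak0046_r3	0	.
chr1	49541	50141	peak0034_r3	0	.
chr1	72759	73379	peak0008_r3	0	.
chr1	99958	100558	peak0048_r3	0	.
chr1	102013	102613	noise_H3K27ac_D0_HET_r3_0	0	.
chr1	110983	111595	peak0003_r3	0	.
chr1	130416	131007	peak0038_r3	0	.
chr1	132250	132834	peak0013_r3	0	.
chr1	143387	143985	peak0012_r3	0	.
chr2	16556	17156	noise_H3K27ac_D0_HET_r3_2	0	.
chr2	18762	19383	peak0002_r3	0	.
chr2	23678	24278	noise_H3K27ac_D0_HET_r3_3	0	.
chr2	41620	42242	peak0009_r3	0	.
chr2	49070	49670	noise_H3K27ac_D0_HET_r3_1	0	.
chr2	67717	68334	peak0004_r3	0	.
chr2	76254	76841	peak0001_r3	0	.
chr2	88648	89260	peak0030_r3	0	.
chr2	96171	96774	peak0010_r3	0	.
chr2	103237	103840	peak0037_r3	0	.
chr2	110647	111226	peak0028_r3	0	.
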