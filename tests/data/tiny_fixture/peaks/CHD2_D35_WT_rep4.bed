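chr1	7759	8160	peak0023_r4	0	.
chr1	11860	12258	peak0022_r4	0	.
chr1	15987	16397	peak0035_r4	0	.
chr1	20987	21394	peak0007_r4	0	.
chr1	26811	27196	peak0046_r4	0	.
chr1	31646	32046	noise_CHD2_D35_WT_r4_0	0	.
chr1	36342	36761	peak0027_r4	0	.
chr1	45206	45597	peak0043_r4	0	.
chr1	49661	50056	peak0034_r4	0	.
chr1	55672	56076	peak0005_r4	0	.
chr1	61253	61664	peak0026_r4	0	.
chr1	72870	73289	peak0008_r4	0	.
chr1	94601	94993	peak0025_r4	0	.
chr1	108678	109075	peak0045_r4	0	.
chr1	111094	111515	peak0003_r4	0	.
chr1	120585	120997	peak0042_r4	0	.
chr1	125724	126123	peak0039_r4	0	.
chr1	130526	130921	peak0038_r4	0	.
chr1	181789	182180	peak0050_r4	0	.
chr1	186673	187073	noise_CHD2_D35_WT_r4_3	0	.
chr2	3599	3977	peak0051_r4	0	.
chr2	18885	19276	peak0002_r4	0	.
chr2	20275	20652	peak0040_r4	0	.
chr2	27871	28283	peak0041_r4	0	.
chr2	41713	42133	peak0009_r4	0	.
chr2	43625	44017	peak0044_r4	0	.
chr2	48049	48447	peak0000_r4	0	.
chr2	52883	53289	peak0047_r4	0	.
chr2	54875	55275	noise_CHD2_D35_WT_r4_1	0	.
chr2	61379	61789	peak0036_r4	0	.
chr2	67824	68221	peak0004_r4	0	.
chr2	76340	76743	peak0001_r4	0	.
chr2	94577	94983	peak0006_r4	0	.
chr2	103334	103743	peak0037_r4	0	.
chr2	117784	118205	peak0049_r4	0	.
chr2	132895	133295	noise_CHD2_D35_WT_r4_2	0	.
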