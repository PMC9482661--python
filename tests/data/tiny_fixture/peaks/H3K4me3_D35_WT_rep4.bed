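chr1	3527	4316	k4_g0000_r4	0	.
chr1	11660	12457	peak0022_r4	0	.
chr1	11792	12595	k4_g0002_r4	0	.
chr1	20804	21598	peak0007_r4	0	.
chr1	25011	25838	k4_g0005_r4	0	.
chr1	36005	36789	k4_g0008_r4	0	.
chr1	44898	45711	k4_g0009_r4	0	.
chr1	47015	47815	noise_H3K4me3_D35_WT_r4_3	0	.
chr1	49339	50125	k4_g0010_r4	0	.
chr1	54286	55060	k4_g0011_r4	0	.
chr1	62374	63169	k4_g0014_r4	0	.
chr1	71238	72013	k4_g0015_r4	0	.
chr1	72670	73490	peak0008_r4	0	.
chr1	77783	78566	k4_g0017_r4	0	.
chr1	86741	87529	k4_g0018_r4	0	.
chr1	94465	95264	k4_g0020_r4	0	.
chr1	99759	100554	k4_g0021_r4	0	.
chr1	117936	118724	k4_g0025_r4	0	.
chr1	120383	121199	peak0042_r4	0	.
chr1	125640	126447	k4_g0027_r4	0	.
chr1	138211	139011	k4_g0030_r4	0	.
chr1	143160	143951	k4_g0031_r4	0	.
chr1	144744	145568	k4_g0032_r4	0	.
chr1	152340	153157	k4_g0033_r4	0	.
chr1	167988	168791	k4_g0037_r4	0	.
chr1	175294	176100	k4_g0038_r4	0	.
chr1	176284	177084	noise_H3K4me3_D35_WT_r4_0	0	.
chr1	181518	182302	k4_g0039_r4	0	.
chr1	181602	182394	peak0050_r4	0	.
chr1	185957	186754	k4_g0040_r4	0	.
chr1	187890	188687	k4_g0041_r4	0	.
chr2	3391	4204	peak0051_r4	0	.
chr2	3425	4226	k4_g0043_r4	0	.
chr2	4880	5685	k4_g0044_r4	0	.
chr2	8028	8832	k4_g0045_r4	0	.
chr2	19998	20804	k4_g0048_r4	0	.
chr2	27765	28571	k4_g0049_r4	0	.
chr2	30004	30829	k4_g0050_r4	0	.
chr2	38125	38928	k4_g0051_r4	0	.
chr2	39214	40014	noise_H3K4me3_D35_WT_r4_2	0	.
chr2	41532	42333	k4_g0052_r4	0	.
chr2	43392	44201	k4_g0053_r4	0	.
chr2	47867	48656	peak0000_r4	0	.
chr2	52668	53466	k4_g0055_r4	0	.
chr2	61270	62077	k4_g0057_r4	0	.
chr2	67640	68440	peak0004_r4	0	.
chr2	69500	70314	k4_g0059_r4	0	.
chr2	77079	77903	k4_g0061_r4	0	.
chr2	88671	89456	k4_g0063_r4	0	.
chr2	94337	95134	k4_g0064_r4	0	.
chr2	103076	103872	k4_g0066_r4	0	.
chr2	108784	109591	k4_g0067_r4	0	.
chr2	110573	111365	k4_g0068_r4	0	.
chr2	117595	118378	peak0049_r4	0	.
chr2	121338	122138	noise_H3K4me3_D35_WT_r4_1	0	.
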