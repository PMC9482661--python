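chr1	7763	8146	peak0023_r3	0	.
chr1	11870	12250	peak0022_r3	0	.
chr1	16011	16389	peak0035_r3	0	.
chr1	26796	27197	peak0046_r3	0	.
chr1	45218	45601	peak0043_r3	0	.
chr1	49658	50065	peak0034_r3	0	.
chr1	55656	56069	peak0005_r3	0	.
chr1	61242	61658	peak0026_r3	0	.
chr1	72877	73277	peak0008_r3	0	.
chr1	94605	95005	peak0025_r3	0	.
chr1	100056	100459	peak0048_r3	0	.
chr1	103838	104236	peak0024_r3	0	.
chr1	108662	109091	peak0045_r3	0	.
chr1	111090	111496	peak0003_r3	0	.
chr1	120595	121012	peak0042_r3	0	.
chr1	125724	126130	peak0039_r3	0	.
chr1	130505	130915	peak0038_r3	0	.
chr1	146415	146815	noise_CHD2_D35_WT_r3_1	0	.
chr1	170536	170936	noise_CHD2_D35_WT_r3_2	0	.
chr1	181798	182186	peak0050_r3	0	.
chr2	3586	3995	peak0051_r3	0	.
chr2	18886	19258	peak0002_r3	0	.
chr2	20242	20633	peak0040_r3	0	.
chr2	27876	28277	peak0041_r3	0	.
chr2	41732	42123	peak0009_r3	0	.
chr2	43637	44037	peak0044_r3	0	.
chr2	48045	48452	peak0000_r3	0	.
chr2	61392	61772	peak0036_r3	0	.
chr2	67838	68221	peak0004_r3	0	.
chr2	76351	76747	peak0001_r3	0	.
chr2	94568	94974	peak0006_r3	0	.
chr2	101254	101654	noise_CHD2_D35_WT_r3_3	0	.
chr2	103356	103728	peak0037_r3	0	.
chr2	117767	118165	peak0049_r3	0	.
chr2	122273	122673	noise_CHD2_D35_WT_r3_0	0	.
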