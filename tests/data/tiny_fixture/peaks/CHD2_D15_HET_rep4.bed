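chr1	3643	4058	peak0032_r4	0	.
chr1	20996	21403	peak0007_r4	0	.
chr1	26799	27196	peak0046_r4	0	.
chr1	30153	30553	noise_CHD2_D15_HET_r4_1	0	.
chr1	39175	39575	noise_CHD2_D15_HET_r4_3	0	.
chr1	54561	54959	peak0020_r4	0	.
chr1	55680	56077	peak0005_r4	0	.
chr1	71508	71904	peak0031_r4	0	.
chr1	74694	75094	noise_CHD2_D15_HET_r4_0	0	.
chr1	100051	100452	peak0048_r4	0	.
chr1	108686	109074	peak0045_r4	0	.
chr1	111092	111513	peak0003_r4	0	.
chr1	120599	120995	peak0042_r4	0	.
chr1	144814	145226	peak0018_r4	0	.
chr1	162812	163241	peak0016_r4	0	.
chr1	181806	182201	peak0050_r4	0	.
chr1	191521	191920	peak0029_r4	0	.
chr2	3586	4000	peak0051_r4	0	.
chr2	8158	8549	peak0019_r4	0	.
chr2	14663	15073	peak0033_r4	0	.
chr2	18876	19264	peak0002_r4	0	.
chr2	20250	20637	peak0040_r4	0	.
chr2	27886	28281	peak0041_r4	0	.
chr2	30246	30627	peak0021_r4	0	.
chr2	41735	42135	peak0009_r4	0	.
chr2	43649	44043	peak0044_r4	0	.
chr2	48037	48447	peak0000_r4	0	.
chr2	52883	53289	peak0047_r4	0	.
chr2	67820	68248	peak0004_r4	0	.
chr2	76358	76726	peak0001_r4	0	.
chr2	88767	89156	peak0030_r4	0	.
chr2	108873	109281	peak0017_r4	0	.
chr2	110725	111149	peak0028_r4	0	.
chr2	117786	118195	peak0049_r4	0	.
chr2	148273	148673	noise_CHD2_D15_HET_r4_2	0	.
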