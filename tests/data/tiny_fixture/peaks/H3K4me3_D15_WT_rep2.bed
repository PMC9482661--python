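chr1	3521	4324	k4_g0000_r2	0	.
chr1	11809	12594	k4_g0002_r2	0	.
chr1	15749	16525	k4_g0003_r2	0	.
chr1	20697	21494	k4_g0004_r2	0	.
chr1	30749	31549	noise_H3K4me3_D15_WT_r2_0	0	.
chr1	34212	35014	k4_g0007_r2	0	.
chr1	44918	45728	k4_g0009_r2	0	.
chr1	49341	50133	k4_g0010_r2	0	.
chr1	54269	55092	k4_g0011_r2	0	.
chr1	55360	56187	k4_g0012_r2	0	.
chr1	62368	63166	k4_g0014_r2	0	.
chr1	71228	72002	k4_g0015_r2	0	.
chr1	72588	73376	k4_g0016_r2	0	.
chr1	72660	73468	peak0008_r2	0	.
chr1	77764	78581	k4_g0017_r2	0	.
chr1	86756	87543	k4_g0018_r2	0	.
chr1	90038	90849	k4_g0019_r2	0	.
chr1	99769	100562	k4_g0021_r2	0	.
chr1	103768	104558	k4_g0022_r2	0	.
chr1	108611	109403	k4_g0023_r2	0	.
chr1	110947	111733	k4_g0024_r2	0	.
chr1	117931	118732	k4_g0025_r2	0	.
chr1	120389	121207	peak0042_r2	0	.
chr1	125661	126466	k4_g0027_r2	0	.
chr1	130440	131227	k4_g0028_r2	0	.
chr1	143157	143957	k4_g0031_r2	0	.
chr1	144758	145563	k4_g0032_r2	0	.
chr1	152346	153165	k4_g0033_r2	0	.
chr1	156989	157789	noise_H3K4me3_D15_WT_r2_3	0	.
chr1	161179	161970	k4_g0035_r2	0	.
chr1	162711	163493	k4_g0036_r2	0	.
chr1	167986	168793	k4_g0037_r2	0	.
chr1	181497	182312	k4_g0039_r2	0	.
chr1	181598	182401	peak0050_r2	0	.
chr1	185957	186735	k4_g0040_r2	0	.
chr1	187891	188688	k4_g0041_r2	0	.
chr1	191216	191992	k4_g0042_r2	0	.
chr1	191317	192113	peak0029_r2	0	.
chr1	195592	196392	noise_H3K4me3_D15_WT_r2_1	0	.
chr2	3395	4202	peak0051_r2	0	.
chr2	14409	15182	k4_g0046_r2	0	.
chr2	18643	19434	k4_g0047_r2	0	.
chr2	20008	20785	k4_g0048_r2	0	.
chr2	27750	28534	k4_g0049_r2	0	.
chr2	38119	38939	k4_g0051_r2	0	.
chr2	41507	42311	k4_g0052_r2	0	.
chr2	43395	44202	k4_g0053_r2	0	.
chr2	47883	48694	k4_g0054_r2	0	.
chr2	59551	60376	k4_g0056_r2	0	.
chr2	67620	68433	peak0004_r2	0	.
chr2	67722	68513	k4_g0058_r2	0	.
chr2	69500	70321	k4_g0059_r2	0	.
chr2	70160	70960	noise_H3K4me3_D15_WT_r2_2	0	.
chr2	76063	76847	k4_g0060_r2	0	.
chr2	77091	77894	k4_g0061_r2	0	.
chr2	88659	89460	k4_g0063_r2	0	.
chr2	94318	95127	k4_g0064_r2	0	.
chr2	103085	103884	k4_g0066_r2	0	.
chr2	110576	111389	k4_g0068_r2	0	.
chr2	117542	118373	k4_g0069_r2	0	.
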