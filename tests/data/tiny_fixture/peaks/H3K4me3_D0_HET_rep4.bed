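chr1	3507	4334	k4_g0000_r4	0	.
chr1	7458	8255	k4_g0001_r4	0	.
chr1	15759	16558	k4_g0003_r4	0	.
chr1	20701	21495	k4_g0004_r4	0	.
chr1	20803	21615	peak0007_r4	0	.
chr1	25051	25836	k4_g0005_r4	0	.
chr1	26577	27376	k4_g0006_r4	0	.
chr1	34234	35002	k4_g0007_r4	0	.
chr1	44912	45699	k4_g0009_r4	0	.
chr1	49340	50150	k4_g0010_r4	0	.
chr1	54300	55063	k4_g0011_r4	0	.
chr1	55398	56177	k4_g0012_r4	0	.
chr1	61108	61910	k4_g0013_r4	0	.
chr1	71211	72032	k4_g0015_r4	0	.
chr1	72569	73373	k4_g0016_r4	0	.
chr1	72678	73499	peak0008_r4	0	.
chr1	75514	76314	noise_H3K4me3_D0_HET_r4_0	0	.
chr1	77779	78577	k4_g0017_r4	0	.
chr1	86748	87531	k4_g0018_r4	0	.
chr1	90028	90842	k4_g0019_r4	0	.
chr1	94472	95280	k4_g0020_r4	0	.
chr1	99764	100563	k4_g0021_r4	0	.
chr1	103775	104571	k4_g0022_r4	0	.
chr1	108595	109405	k4_g0023_r4	0	.
chr1	110966	111743	k4_g0024_r4	0	.
chr1	117942	118734	k4_g0025_r4	0	.
chr1	120299	121109	k4_g0026_r4	0	.
chr1	130440	131236	k4_g0028_r4	0	.
chr1	132029	132827	k4_g0029_r4	0	.
chr1	138220	139002	k4_g0030_r4	0	.
chr1	144762	145571	k4_g0032_r4	0	.
chr1	152355	153176	k4_g0033_r4	0	.
chr1	156800	157617	k4_g0034_r4	0	.
chr1	161165	161993	k4_g0035_r4	0	.
chr1	162691	163491	k4_g0036_r4	0	.
chr1	167992	168788	k4_g0037_r4	0	.
chr1	175281	176101	k4_g0038_r4	0	.
chr1	181499	182299	k4_g0039_r4	0	.
chr1	181608	182407	peak0050_r4	0	.
chr1	185966	186735	k4_g0040_r4	0	.
chr1	187880	188675	k4_g0041_r4	0	.
chr1	191328	192111	peak0029_r4	0	.
chr1	196161	196961	noise_H3K4me3_D0_HET_r4_1	0	.
chr1	196794	197594	noise_H3K4me3_D0_HET_r4_3	0	.
chr2	3397	4198	peak0051_r4	0	.
chr2	3420	4241	k4_g0043_r4	0	.
chr2	4911	5699	k4_g0044_r4	0	.
chr2	8038	8839	k4_g0045_r4	0	.
chr2	14407	15220	k4_g0046_r4	0	.
chr2	18639	19453	k4_g0047_r4	0	.
chr2	19992	20786	k4_g0048_r4	0	.
chr2	27752	28554	k4_g0049_r4	0	.
chr2	30029	30839	k4_g0050_r4	0	.
chr2	38113	38934	k4_g0051_r4	0	.
chr2	41530	42321	k4_g0052_r4	0	.
chr2	43393	44194	k4_g0053_r4	0	.
chr2	47841	48645	peak0000_r4	0	.
chr2	47869	48683	k4_g0054_r4	0	.
chr2	52651	53481	k4_g0055_r4	0	.
chr2	59555	60361	k4_g0056_r4	0	.
chr2	61266	62074	k4_g0057_r4	0	.
chr2	67606	68409	peak0004_r4	0	.
chr2	67691	68509	k4_g0058_r4	0	.
chr2	69521	70310	k4_g0059_r4	0	.
chr2	76064	76842	k4_g0060_r4	0	.
chr2	77089	77893	k4_g0061_r4	0	.
chr2	80647	81447	k4_g0062_r4	0	.
chr2	88669	89458	k4_g0063_r4	0	.
chr2	94351	95139	k4_g0064_r4	0	.
chr2	96084	96895	k4_g0065_r4	0	.
chr2	103085	103912	k4_g0066_r4	0	.
chr2	108782	109590	k4_g0067_r4	0	.
chr2	117555	118359	k4_g0069_r4	0	.
chr2	117572	118379	peak0049_r4	0	.
chr2	140083	140883	noise_H3K4me3_D0_HET_r4_2	0	.
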