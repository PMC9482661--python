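chr1	11658	12433	peak0022_r4	0	.
chr1	11803	12615	k4_g0002_r4	0	.
chr1	20807	21604	peak0007_r4	0	.
chr1	25038	25846	k4_g0005_r4	0	.
chr1	34214	35018	k4_g0007_r4	0	.
chr1	36021	36808	k4_g0008_r4	0	.
chr1	44914	45721	k4_g0009_r4	0	.
chr1	47168	47968	noise_H3K4me3_D35_HET_r4_0	0	.
chr1	49328	50121	k4_g0010_r4	0	.
chr1	54264	55075	k4_g0011_r4	0	.
chr1	55374	56199	k4_g0012_r4	0	.
chr1	62352	63187	k4_g0014_r4	0	.
chr1	71217	72037	k4_g0015_r4	0	.
chr1	72574	73393	k4_g0016_r4	0	.
chr1	72665	73478	peak0008_r4	0	.
chr1	77767	78556	k4_g0017_r4	0	.
chr1	86741	87536	k4_g0018_r4	0	.
chr1	94473	95253	k4_g0020_r4	0	.
chr1	99760	100546	k4_g0021_r4	0	.
chr1	117927	118740	k4_g0025_r4	0	.
chr1	120403	121201	peak0042_r4	0	.
chr1	125660	126449	k4_g0027_r4	0	.
chr1	138213	139008	k4_g0030_r4	0	.
chr1	143163	143953	k4_g0031_r4	0	.
chr1	144759	145554	k4_g0032_r4	0	.
chr1	152351	153144	k4_g0033_r4	0	.
chr1	168005	168773	k4_g0037_r4	0	.
chr1	175301	176120	k4_g0038_r4	0	.
chr1	181489	182306	k4_g0039_r4	0	.
chr1	181614	182402	peak0050_r4	0	.
chr1	187873	188671	k4_g0041_r4	0	.
chr2	3407	4201	peak0051_r4	0	.
chr2	3422	4227	k4_g0043_r4	0	.
chr2	4911	5692	k4_g0044_r4	0	.
chr2	8057	8819	k4_g0045_r4	0	.
chr2	19975	20800	k4_g0048_r4	0	.
chr2	27766	28550	k4_g0049_r4	0	.
chr2	30032	30835	k4_g0050_r4	0	.
chr2	38141	38927	k4_g0051_r4	0	.
chr2	41530	42326	k4_g0052_r4	0	.
chr2	43394	44196	k4_g0053_r4	0	.
chr2	47852	48657	peak0000_r4	0	.
chr2	52675	53471	k4_g0055_r4	0	.
chr2	55809	56609	noise_H3K4me3_D35_HET_r4_2	0	.
chr2	59557	60365	k4_g0056_r4	0	.
chr2	61279	62091	k4_g0057_r4	0	.
chr2	67614	68447	peak0004_r4	0	.
chr2	69489	70311	k4_g0059_r4	0	.
chr2	77099	77880	k4_g0061_r4	0	.
chr2	80474	81274	noise_H3K4me3_D35_HET_r4_3	0	.
chr2	94340	95152	k4_g0064_r4	0	.
chr2	103082	103866	k4_g0066_r4	0	.
chr2	108787	109578	k4_g0067_r4	0	.
chr2	110575	111392	k4_g0068_r4	0	.
chr2	146974	147774	noise_H3K4me3_D35_HET_r4_1	0	.
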