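chr1	3522	4329	k4_g0000_r3	0	.
chr1	7452	8262	k4_g0001_r3	0	.
chr1	11817	12597	k4_g0002_r3	0	.
chr1	15729	16530	k4_g0003_r3	0	.
chr1	20698	21492	k4_g0004_r3	0	.
chr1	20793	21600	peak0007_r3	0	.
chr1	25027	25818	k4_g0005_r3	0	.
chr1	26558	27358	k4_g0006_r3	0	.
chr1	34238	35009	k4_g0007_r3	0	.
chr1	36001	36802	k4_g0008_r3	0	.
chr1	40763	41563	noise_H3K4me3_D0_HET_r3_2	0	.
chr1	44909	45719	k4_g0009_r3	0	.
chr1	49340	50125	k4_g0010_r3	0	.
chr1	54271	55074	k4_g0011_r3	0	.
chr1	55379	56171	k4_g0012_r3	0	.
chr1	61098	61890	k4_g0013_r3	0	.
chr1	72599	73374	k4_g0016_r3	0	.
chr1	72690	73472	peak0008_r3	0	.
chr1	77779	78582	k4_g0017_r3	0	.
chr1	77784	78585	peak0015_r3	0	.
chr1	86749	87548	k4_g0018_r3	0	.
chr1	88156	88956	noise_H3K4me3_D0_HET_r3_1	0	.
chr1	90059	90853	k4_g0019_r3	0	.
chr1	99758	100557	k4_g0021_r3	0	.
chr1	108599	109372	k4_g0023_r3	0	.
chr1	110925	111751	k4_g0024_r3	0	.
chr1	117938	118747	k4_g0025_r3	0	.
chr1	120316	121122	k4_g0026_r3	0	.
chr1	125650	126463	k4_g0027_r3	0	.
chr1	132033	132832	k4_g0029_r3	0	.
chr1	138197	139043	k4_g0030_r3	0	.
chr1	143165	143964	k4_g0031_r3	0	.
chr1	144747	145577	k4_g0032_r3	0	.
chr1	152343	153163	k4_g0033_r3	0	.
chr1	156800	157609	k4_g0034_r3	0	.
chr1	161184	161969	k4_g0035_r3	0	.
chr1	167974	168782	k4_g0037_r3	0	.
chr1	175300	176098	k4_g0038_r3	0	.
chr1	181594	182410	peak0050_r3	0	.
chr1	185940	186759	k4_g0040_r3	0	.
chr1	191231	192007	k4_g0042_r3	0	.
chr1	191322	192117	peak0029_r3	0	.
chr2	3393	4202	peak0051_r3	0	.
chr2	3438	4220	k4_g0043_r3	0	.
chr2	8031	8819	k4_g0045_r3	0	.
chr2	14430	15197	k4_g0046_r3	0	.
chr2	18648	19462	k4_g0047_r3	0	.
chr2	19973	20792	k4_g0048_r3	0	.
chr2	27751	28557	k4_g0049_r3	0	.
chr2	30020	30819	k4_g0050_r3	0	.
chr2	38142	38910	k4_g0051_r3	0	.
chr2	43384	44210	k4_g0053_r3	0	.
chr2	47845	48656	peak0000_r3	0	.
chr2	47891	48686	k4_g0054_r3	0	.
chr2	52660	53467	k4_g0055_r3	0	.
chr2	59550	60374	k4_g0056_r3	0	.
chr2	67717	68539	k4_g0058_r3	0	.
chr2	69505	70313	k4_g0059_r3	0	.
chr2	72595	73395	noise_H3K4me3_D0_HET_r3_0	0	.
chr2	73162	73962	noise_H3K4me3_D0_HET_r3_3	0	.
chr2	76052	76864	k4_g0060_r3	0	.
chr2	77082	77897	k4_g0061_r3	0	.
chr2	80646	81450	k4_g0062_r3	0	.
chr2	88653	89485	k4_g0063_r3	0	.
chr2	94328	95124	k4_g0064_r3	0	.
chr2	96092	96890	k4_g0065_r3	0	.
chr2	103079	103861	k4_g0066_r3	0	.
chr2	108794	109576	k4_g0067_r3	0	.
chr2	110567	111374	k4_g0068_r3	0	.
chr2	117572	118357	k4_g0069_r3	0	.
chr2	117590	118391	peak0049_r3	0	.
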