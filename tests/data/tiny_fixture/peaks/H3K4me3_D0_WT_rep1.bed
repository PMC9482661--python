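chr1	3519	4313	k4_g0000_r1	0	.
chr1	7471	8261	k4_g0001_r1	0	.
chr1	11793	12602	k4_g0002_r1	0	.
chr1	15742	16552	k4_g0003_r1	0	.
chr1	20815	21602	peak0007_r1	0	.
chr1	25052	25832	k4_g0005_r1	0	.
chr1	26577	27359	k4_g0006_r1	0	.
chr1	34199	35026	k4_g0007_r1	0	.
chr1	35966	36813	k4_g0008_r1	0	.
chr1	44901	45708	k4_g0009_r1	0	.
chr1	49343	50146	k4_g0010_r1	0	.
chr1	54274	55082	k4_g0011_r1	0	.
chr1	55381	56178	k4_g0012_r1	0	.
chr1	61111	61920	k4_g0013_r1	0	.
chr1	62361	63162	k4_g0014_r1	0	.
chr1	71220	72028	k4_g0015_r1	0	.
chr1	72587	73374	k4_g0016_r1	0	.
chr1	72670	73473	peak0008_r1	0	.
chr1	76132	76932	noise_H3K4me3_D0_WT_r1_1	0	.
chr1	77791	78577	peak0015_r1	0	.
chr1	86748	87548	k4_g0018_r1	0	.
chr1	90051	90835	k4_g0019_r1	0	.
chr1	94464	95262	k4_g0020_r1	0	.
chr1	99765	100571	k4_g0021_r1	0	.
chr1	108597	109403	k4_g0023_r1	0	.
chr1	110955	111742	k4_g0024_r1	0	.
chr1	117959	118729	k4_g0025_r1	0	.
chr1	120306	121117	k4_g0026_r1	0	.
chr1	125632	126440	k4_g0027_r1	0	.
chr1	130443	131236	k4_g0028_r1	0	.
chr1	132025	132819	k4_g0029_r1	0	.
chr1	138226	139007	k4_g0030_r1	0	.
chr1	143172	143954	k4_g0031_r1	0	.
chr1	144753	145560	k4_g0032_r1	0	.
chr1	152347	153154	k4_g0033_r1	0	.
chr1	156815	157600	k4_g0034_r1	0	.
chr1	161159	161987	k4_g0035_r1	0	.
chr1	162713	163512	k4_g0036_r1	0	.
chr1	167984	168798	k4_g0037_r1	0	.
chr1	175318	176110	k4_g0038_r1	0	.
chr1	181514	182302	k4_g0039_r1	0	.
chr1	181571	182401	peak0050_r1	0	.
chr1	187896	188673	k4_g0041_r1	0	.
chr1	191218	192007	k4_g0042_r1	0	.
chr1	191319	192125	peak0029_r1	0	.
chr2	3405	4200	peak0051_r1	0	.
chr2	3423	4212	k4_g0043_r1	0	.
chr2	4895	5686	k4_g0044_r1	0	.
chr2	14409	15217	k4_g0046_r1	0	.
chr2	27759	28572	k4_g0049_r1	0	.
chr2	30044	30842	k4_g0050_r1	0	.
chr2	38118	38912	k4_g0051_r1	0	.
chr2	41518	42330	k4_g0052_r1	0	.
chr2	43392	44191	k4_g0053_r1	0	.
chr2	47858	48651	peak0000_r1	0	.
chr2	52662	53473	k4_g0055_r1	0	.
chr2	55120	55920	noise_H3K4me3_D0_WT_r1_0	0	.
chr2	67650	68435	peak0004_r1	0	.
chr2	67725	68516	k4_g0058_r1	0	.
chr2	69498	70315	k4_g0059_r1	0	.
chr2	76071	76885	k4_g0060_r1	0	.
chr2	77098	77904	k4_g0061_r1	0	.
chr2	80651	81476	k4_g0062_r1	0	.
chr2	88651	89466	k4_g0063_r1	0	.
chr2	94339	95134	k4_g0064_r1	0	.
chr2	96098	96904	k4_g0065_r1	0	.
chr2	103063	103898	k4_g0066_r1	0	.
chr2	108801	109583	k4_g0067_r1	0	.
chr2	110586	111371	k4_g0068_r1	0	.
chr2	117555	118338	k4_g0069_r1	0	.
chr2	117578	118388	peak0049_r1	0	.
chr2	122071	122871	noise_H3K4me3_D0_WT_r1_3	0	.
chr2	137252	138052	noise_H3K4me3_D0_WT_r1_2	0	.
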