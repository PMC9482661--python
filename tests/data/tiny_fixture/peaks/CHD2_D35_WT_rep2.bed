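chr1	7754	8158	peak0023_r2	0	.
chr1	11859	12259	peak0022_r2	0	.
chr1	16011	16403	peak0035_r2	0	.
chr1	26811	27214	peak0046_r2	0	.
chr1	45212	45592	peak0043_r2	0	.
chr1	49625	50045	peak0034_r2	0	.
chr1	55678	56047	peak0005_r2	0	.
chr1	61254	61651	peak0026_r2	0	.
chr1	94606	94987	peak0025_r2	0	.
chr1	100058	100457	peak0048_r2	0	.
chr1	103845	104237	peak0024_r2	0	.
chr1	108674	109080	peak0045_r2	0	.
chr1	120606	120983	peak0042_r2	0	.
chr1	125735	126132	peak0039_r2	0	.
chr1	130508	130906	peak0038_r2	0	.
chr1	178974	179374	noise_CHD2_D35_WT_r2_2	0	.
chr1	181803	182196	peak0050_r2	0	.
chr2	3591	4006	peak0051_r2	0	.
chr2	18874	19258	peak0002_r2	0	.
chr2	20244	20636	peak0040_r2	0	.
chr2	41731	42138	peak0009_r2	0	.
chr2	43637	44031	peak0044_r2	0	.
chr2	48052	48455	peak0000_r2	0	.
chr2	52905	53284	peak0047_r2	0	.
chr2	61390	61804	peak0036_r2	0	.
chr2	67802	68214	peak0004_r2	0	.
chr2	76339	76759	peak0001_r2	0	.
chr2	94571	94986	peak0006_r2	0	.
chr2	103345	103759	peak0037_r2	0	.
chr2	117776	118177	peak0049_r2	0	.
chr2	131141	131541	noise_CHD2_D35_WT_r2_0	0	.
chr2	139288	139688	noise_CHD2_D35_WT_r2_1	0	.
chr2	141165	141565	noise_CHD2_D35_WT_r2_3	0	.
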