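chr1	3656	4072	peak0032_r3	0	.
chr1	21003	21413	peak0007_r3	0	.
chr1	26801	27200	peak0046_r3	0	.
chr1	45207	45605	peak0043_r3	0	.
chr1	48160	48560	noise_CHD2_D15_HET_r3_3	0	.
chr1	55675	56073	peak0005_r3	0	.
chr1	71508	71901	peak0031_r3	0	.
chr1	72873	73277	peak0008_r3	0	.
chr1	100059	100459	peak0048_r3	0	.
chr1	108672	109049	peak0045_r3	0	.
chr1	111088	111500	peak0003_r3	0	.
chr1	114447	114847	noise_CHD2_D15_HET_r3_2	0	.
chr1	120610	121004	peak0042_r3	0	.
chr1	144821	145219	peak0018_r3	0	.
chr1	162826	163219	peak0016_r3	0	.
chr1	181790	182205	peak0050_r3	0	.
chr2	3594	4004	peak0051_r3	0	.
chr2	8161	8550	peak0019_r3	0	.
chr2	14652	15059	peak0033_r3	0	.
chr2	18884	19282	peak0002_r3	0	.
chr2	20260	20659	peak0040_r3	0	.
chr2	27872	28289	peak0041_r3	0	.
chr2	30230	30629	peak0021_r3	0	.
chr2	41734	42151	peak0009_r3	0	.
chr2	43651	44054	peak0044_r3	0	.
chr2	48058	48466	peak0000_r3	0	.
chr2	52875	53294	peak0047_r3	0	.
chr2	76348	76750	peak0001_r3	0	.
chr2	88769	89158	peak0030_r3	0	.
chr2	100175	100575	noise_CHD2_D15_HET_r3_1	0	.
chr2	108877	109288	peak0017_r3	0	.
chr2	110741	111128	peak0028_r3	0	.
chr2	117781	118182	peak0049_r3	0	.
chr2	125672	126072	noise_CHD2_D15_HET_r3_0	0	.
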