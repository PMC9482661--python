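chr1	603	1003	noise_CHD2_D15_WT_r3_0	0	.
chr1	26799	27205	peak0046_r3	0	.
chr1	42613	43013	noise_CHD2_D15_WT_r3_1	0	.
chr1	45206	45602	peak0043_r3	0	.
chr1	55679	56057	peak0005_r3	0	.
chr1	71506	71913	peak0031_r3	0	.
chr1	72881	73273	peak0008_r3	0	.
chr1	100066	100446	peak0048_r3	0	.
chr1	108664	109064	peak0045_r3	0	.
chr1	111084	111498	peak0003_r3	0	.
chr1	120609	121011	peak0042_r3	0	.
chr1	139476	139876	noise_CHD2_D15_WT_r3_2	0	.
chr1	144830	145227	peak0018_r3	0	.
chr1	181795	182178	peak0050_r3	0	.
chr1	191524	191911	peak0029_r3	0	.
chr2	3606	4021	peak0051_r3	0	.
chr2	8147	8561	peak0019_r3	0	.
chr2	14633	15074	peak0033_r3	0	.
chr2	18864	19272	peak0002_r3	0	.
chr2	20245	20657	peak0040_r3	0	.
chr2	27879	28300	peak0041_r3	0	.
chr2	30226	30618	peak0021_r3	0	.
chr2	41748	42128	peak0009_r3	0	.
chr2	43627	44032	peak0044_r3	0	.
chr2	48055	48474	peak0000_r3	0	.
chr2	52887	53286	peak0047_r3	0	.
chr2	76349	76743	peak0001_r3	0	.
chr2	88772	89156	peak0030_r3	0	.
chr2	108867	109273	peak0017_r3	0	.
chr2	110728	111140	peak0028_r3	0	.
chr2	117786	118170	peak0049_r3	0	.
chr2	125375	125775	noise_CHD2_D15_WT_r3_3	0	.
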