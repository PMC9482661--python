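chr1	3669	4048	peak0032_r4	0	.
chr1	16003	16403	peak0035_r4	0	.
chr1	26823	27187	peak0046_r4	0	.
chr1	49667	50056	peak0034_r4	0	.
chr1	71514	71901	peak0031_r4	0	.
chr1	72893	73278	peak0008_r4	0	.
chr1	77984	78380	peak0015_r4	0	.
chr1	100059	100458	peak0048_r4	0	.
chr1	111097	111507	peak0003_r4	0	.
chr1	125739	126142	peak0039_r4	0	.
chr1	130531	130898	peak0038_r4	0	.
chr1	132350	132738	peak0013_r4	0	.
chr1	138386	138800	peak0011_r4	0	.
chr1	143491	143894	peak0012_r4	0	.
chr1	168226	168631	peak0014_r4	0	.
chr1	181792	182187	peak0050_r4	0	.
chr2	3602	3993	peak0051_r4	0	.
chr2	14670	15056	peak0033_r4	0	.
chr2	16321	16721	noise_CHD2_D0_WT_r4_1	0	.
chr2	18868	19280	peak0002_r4	0	.
chr2	41739	42147	peak0009_r4	0	.
chr2	45293	45693	noise_CHD2_D0_WT_r4_3	0	.
chr2	52874	53281	peak0047_r4	0	.
chr2	56184	56584	noise_CHD2_D0_WT_r4_2	0	.
chr2	61397	61778	peak0036_r4	0	.
chr2	67817	68221	peak0004_r4	0	.
chr2	88772	89145	peak0030_r4	0	.
chr2	96283	96701	peak0010_r4	0	.
chr2	103330	103746	peak0037_r4	0	.
chr2	117790	118176	peak0049_r4	0	.
chr2	131000	131400	noise_CHD2_D0_WT_r4_0	0	.
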