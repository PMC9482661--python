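chr1	454	854	noise_CHD2_D0_WT_r2_2	0	.
chr1	3675	4057	peak0032_r2	0	.
chr1	9888	10288	noise_CHD2_D0_WT_r2_3	0	.
chr1	15992	16386	peak0035_r2	0	.
chr1	21011	21410	peak0007_r2	0	.
chr1	26804	27204	peak0046_r2	0	.
chr1	49665	50053	peak0034_r2	0	.
chr1	71500	71892	peak0031_r2	0	.
chr1	72873	73279	peak0008_r2	0	.
chr1	77993	78389	peak0015_r2	0	.
chr1	93484	93884	noise_CHD2_D0_WT_r2_1	0	.
chr1	100054	100442	peak0048_r2	0	.
chr1	111098	111509	peak0003_r2	0	.
chr1	125725	126117	peak0039_r2	0	.
chr1	130509	130929	peak0038_r2	0	.
chr1	138421	138791	peak0011_r2	0	.
chr1	140958	141358	noise_CHD2_D0_WT_r2_0	0	.
chr1	143493	143897	peak0012_r2	0	.
chr1	168217	168615	peak0014_r2	0	.
chr1	181811	182190	peak0050_r2	0	.
chr1	191515	191920	peak0029_r2	0	.
chr2	3600	3979	peak0051_r2	0	.
chr2	14655	15041	peak0033_r2	0	.
chr2	18889	19257	peak0002_r2	0	.
chr2	41759	42148	peak0009_r2	0	.
chr2	48063	48455	peak0000_r2	0	.
chr2	52904	53293	peak0047_r2	0	.
chr2	67825	68208	peak0004_r2	0	.
chr2	76347	76742	peak0001_r2	0	.
chr2	88762	89156	peak0030_r2	0	.
chr2	96298	96687	peak0010_r2	0	.
chr2	103328	103749	peak0037_r2	0	.
chr2	110737	111130	peak0028_r2	0	.
chr2	117786	118185	peak0049_r2	0	.
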