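chr1	3657	4066	peak0032_r4	0	.
chr1	15987	16372	peak0035_r4	0	.
chr1	21017	21405	peak0007_r4	0	.
chr1	26804	27197	peak0046_r4	0	.
chr1	49660	50051	peak0034_r4	0	.
chr1	71490	71919	peak0031_r4	0	.
chr1	78003	78391	peak0015_r4	0	.
chr1	80372	80772	noise_CHD2_D0_HET_r4_3	0	.
chr1	111106	111508	peak0003_r4	0	.
chr1	125748	126117	peak0039_r4	0	.
chr1	130507	130929	peak0038_r4	0	.
chr1	132325	132739	peak0013_r4	0	.
chr1	168228	168612	peak0014_r4	0	.
chr1	181803	182200	peak0050_r4	0	.
chr1	191511	191915	peak0029_r4	0	.
chr2	3604	4010	peak0051_r4	0	.
chr2	14653	15060	peak0033_r4	0	.
chr2	18879	19282	peak0002_r4	0	.
chr2	41749	42140	peak0009_r4	0	.
chr2	48046	48452	peak0000_r4	0	.
chr2	52900	53314	peak0047_r4	0	.
chr2	56871	57271	noise_CHD2_D0_HET_r4_2	0	.
chr2	61388	61775	peak0036_r4	0	.
chr2	76343	76728	peak0001_r4	0	.
chr2	83603	84003	noise_CHD2_D0_HET_r4_0	0	.
chr2	88749	89149	peak0030_r4	0	.
chr2	90341	90741	noise_CHD2_D0_HET_r4_1	0	.
chr2	96295	96690	peak0010_r4	0	.
chr2	103334	103736	peak0037_r4	0	.
chr2	110718	111134	peak0028_r4	0	.
chr2	117777	118187	peak0049_r4	0	.
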