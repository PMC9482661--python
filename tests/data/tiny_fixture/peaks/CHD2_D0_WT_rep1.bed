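chr1	3673	4064	peak0032_r1	0	.
chr1	15981	16413	peak0035_r1	0	.
chr1	20983	21386	peak0007_r1	0	.
chr1	24316	24716	noise_CHD2_D0_WT_r1_3	0	.
chr1	26806	27208	peak0046_r1	0	.
chr1	49651	50081	peak0034_r1	0	.
chr1	71490	71899	peak0031_r1	0	.
chr1	72870	73279	peak0008_r1	0	.
chr1	77985	78389	peak0015_r1	0	.
chr1	100044	100464	peak0048_r1	0	.
chr1	111091	111507	peak0003_r1	0	.
chr1	117615	118015	noise_CHD2_D0_WT_r1_2	0	.
chr1	125748	126131	peak0039_r1	0	.
chr1	130524	130913	peak0038_r1	0	.
chr1	132331	132733	peak0013_r1	0	.
chr1	138377	138801	peak0011_r1	0	.
chr1	168224	168624	peak0014_r1	0	.
chr1	172980	173380	noise_CHD2_D0_WT_r1_0	0	.
chr1	181809	182182	peak0050_r1	0	.
chr1	191509	191913	peak0029_r1	0	.
chr2	3582	3987	peak0051_r1	0	.
chr2	14662	15064	peak0033_r1	0	.
chr2	18874	19275	peak0002_r1	0	.
chr2	41744	42149	peak0009_r1	0	.
chr2	48058	48447	peak0000_r1	0	.
chr2	52888	53271	peak0047_r1	0	.
chr2	53964	54364	noise_CHD2_D0_WT_r1_1	0	.
chr2	61406	61804	peak0036_r1	0	.
chr2	67834	68214	peak0004_r1	0	.
chr2	76329	76742	peak0001_r1	0	.
chr2	88762	89159	peak0030_r1	0	.
chr2	96300	96696	peak0010_r1	0	.
chr2	103346	103718	peak0037_r1	0	.
chr2	110746	111138	peak0028_r1	0	.
chr2	117772	118191	peak0049_r1	0	.
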