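chr1	3657	4062	peak0032_r2	0	.
chr1	21007	21397	peak0007_r2	0	.
chr1	26802	27200	peak0046_r2	0	.
chr1	45201	45610	peak0043_r2	0	.
chr1	54549	54970	peak0020_r2	0	.
chr1	55669	56063	peak0005_r2	0	.
chr1	71500	71893	peak0031_r2	0	.
chr1	72876	73292	peak0008_r2	0	.
chr1	100043	100458	peak0048_r2	0	.
chr1	108671	109059	peak0045_r2	0	.
chr1	111104	111511	peak0003_r2	0	.
chr1	120584	120991	peak0042_r2	0	.
chr1	144836	145223	peak0018_r2	0	.
chr1	162827	163219	peak0016_r2	0	.
chr1	181770	182207	peak0050_r2	0	.
chr1	191513	191917	peak0029_r2	0	.
chr2	3592	4004	peak0051_r2	0	.
chr2	6813	7213	noise_CHD2_D15_WT_r2_3	0	.
chr2	8145	8549	peak0019_r2	0	.
chr2	14665	15070	peak0033_r2	0	.
chr2	18870	19252	peak0002_r2	0	.
chr2	24437	24837	noise_CHD2_D15_WT_r2_2	0	.
chr2	27864	28282	peak0041_r2	0	.
chr2	30232	30620	peak0021_r2	0	.
chr2	41747	42148	peak0009_r2	0	.
chr2	43621	44024	peak0044_r2	0	.
chr2	52867	53301	peak0047_r2	0	.
chr2	67835	68236	peak0004_r2	0	.
chr2	76342	76730	peak0001_r2	0	.
chr2	85305	85705	noise_CHD2_D15_WT_r2_1	0	.
chr2	88772	89152	peak0030_r2	0	.
chr2	108883	109275	peak0017_r2	0	.
chr2	110741	111135	peak0028_r2	0	.
chr2	117784	118184	peak0049_r2	0	.
chr2	132335	132735	noise_CHD2_D15_WT_r2_0	0	.
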