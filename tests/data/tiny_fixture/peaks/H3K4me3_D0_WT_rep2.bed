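chr1	3517	4333	k4_g0000_r2	0	.
chr1	7449	8274	k4_g0001_r2	0	.
chr1	11797	12603	k4_g0002_r2	0	.
chr1	15741	16552	k4_g0003_r2	0	.
chr1	20679	21489	k4_g0004_r2	0	.
chr1	20797	21619	peak0007_r2	0	.
chr1	22542	23342	noise_H3K4me3_D0_WT_r2_0	0	.
chr1	25036	25839	k4_g0005_r2	0	.
chr1	26574	27357	k4_g0006_r2	0	.
chr1	34224	35028	k4_g0007_r2	0	.
chr1	36005	36787	k4_g0008_r2	0	.
chr1	44898	45701	k4_g0009_r2	0	.
chr1	49315	50132	k4_g0010_r2	0	.
chr1	54292	55085	k4_g0011_r2	0	.
chr1	55394	56169	k4_g0012_r2	0	.
chr1	61090	61900	k4_g0013_r2	0	.
chr1	62372	63171	k4_g0014_r2	0	.
chr1	71218	72020	k4_g0015_r2	0	.
chr1	72584	73371	k4_g0016_r2	0	.
chr1	72660	73479	peak0008_r2	0	.
chr1	77778	78577	k4_g0017_r2	0	.
chr1	77790	78580	peak0015_r2	0	.
chr1	86738	87540	k4_g0018_r2	0	.
chr1	94472	95284	k4_g0020_r2	0	.
chr1	99762	100566	k4_g0021_r2	0	.
chr1	103772	104559	k4_g0022_r2	0	.
chr1	108582	109379	k4_g0023_r2	0	.
chr1	110912	111743	k4_g0024_r2	0	.
chr1	117925	118745	k4_g0025_r2	0	.
chr1	120297	121115	k4_g0026_r2	0	.
chr1	125657	126463	k4_g0027_r2	0	.
chr1	132028	132816	k4_g0029_r2	0	.
chr1	138218	139001	k4_g0030_r2	0	.
chr1	143157	143968	k4_g0031_r2	0	.
chr1	144762	145562	k4_g0032_r2	0	.
chr1	152367	153162	k4_g0033_r2	0	.
chr1	161163	161956	k4_g0035_r2	0	.
chr1	162711	163504	k4_g0036_r2	0	.
chr1	167993	168780	k4_g0037_r2	0	.
chr1	175313	176118	k4_g0038_r2	0	.
chr1	181522	182301	k4_g0039_r2	0	.
chr1	181590	182388	peak0050_r2	0	.
chr1	185946	186747	k4_g0040_r2	0	.
chr1	187897	188682	k4_g0041_r2	0	.
chr1	191321	192123	peak0029_r2	0	.
chr2	3402	4203	peak0051_r2	0	.
chr2	3424	4246	k4_g0043_r2	0	.
chr2	4884	5692	k4_g0044_r2	0	.
chr2	8016	8819	k4_g0045_r2	0	.
chr2	14413	15199	k4_g0046_r2	0	.
chr2	18636	19435	k4_g0047_r2	0	.
chr2	19996	20810	k4_g0048_r2	0	.
chr2	30021	30814	k4_g0050_r2	0	.
chr2	38132	38912	k4_g0051_r2	0	.
chr2	41543	42331	k4_g0052_r2	0	.
chr2	43401	44211	k4_g0053_r2	0	.
chr2	47836	48658	peak0000_r2	0	.
chr2	52681	53464	k4_g0055_r2	0	.
chr2	59561	60363	k4_g0056_r2	0	.
chr2	61299	62085	k4_g0057_r2	0	.
chr2	63137	63937	noise_H3K4me3_D0_WT_r2_1	0	.
chr2	67611	68416	peak0004_r2	0	.
chr2	67718	68527	k4_g0058_r2	0	.
chr2	76043	76859	k4_g0060_r2	0	.
chr2	77110	77912	k4_g0061_r2	0	.
chr2	80652	81455	k4_g0062_r2	0	.
chr2	88654	89479	k4_g0063_r2	0	.
chr2	94330	95126	k4_g0064_r2	0	.
chr2	96075	96901	k4_g0065_r2	0	.
chr2	103079	103869	k4_g0066_r2	0	.
chr2	106051	106851	noise_H3K4me3_D0_WT_r2_3	0	.
chr2	108778	109574	k4_g0067_r2	0	.
chr2	110585	111375	k4_g0068_r2	0	.
chr2	117559	118344	k4_g0069_r2	0	.
chr2	117572	118389	peak0049_r2	0	.
chr2	134135	134935	noise_H3K4me3_D0_WT_r2_2	0	.
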