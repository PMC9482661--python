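chr1	20989	21400	peak0007_r1	0	.
chr1	26807	27202	peak0046_r1	0	.
chr1	45200	45610	peak0043_r1	0	.
chr1	54576	54966	peak0020_r1	0	.
chr1	55659	56074	peak0005_r1	0	.
chr1	71512	71909	peak0031_r1	0	.
chr1	72868	73286	peak0008_r1	0	.
chr1	79547	79947	noise_CHD2_D15_HET_r1_3	0	.
chr1	100055	100455	peak0048_r1	0	.
chr1	108662	109092	peak0045_r1	0	.
chr1	111077	111501	peak0003_r1	0	.
chr1	120608	120994	peak0042_r1	0	.
chr1	144819	145212	peak0018_r1	0	.
chr1	162834	163215	peak0016_r1	0	.
chr1	181807	182198	peak0050_r1	0	.
chr1	191523	191931	peak0029_r1	0	.
chr2	3600	3997	peak0051_r1	0	.
chr2	14659	15069	peak0033_r1	0	.
chr2	18883	19269	peak0002_r1	0	.
chr2	20218	20635	peak0040_r1	0	.
chr2	27877	28275	peak0041_r1	0	.
chr2	35617	36017	noise_CHD2_D15_HET_r1_2	0	.
chr2	41747	42143	peak0009_r1	0	.
chr2	43628	44043	peak0044_r1	0	.
chr2	48070	48452	peak0000_r1	0	.
chr2	52895	53283	peak0047_r1	0	.
chr2	67830	68240	peak0004_r1	0	.
chr2	76344	76734	peak0001_r1	0	.
chr2	88764	89164	peak0030_r1	0	.
chr2	106073	106473	noise_CHD2_D15_HET_r1_1	0	.
chr2	108863	109272	peak0017_r1	0	.
chr2	110723	111150	peak0028_r1	0	.
chr2	112472	112872	noise_CHD2_D15_HET_r1_0	0	.
chr2	117780	118180	peak0049_r1	0	.
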