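chr1	3668	4063	peak0032_r2	0	.
chr1	16002	16389	peak0035_r2	0	.
chr1	20989	21394	peak0007_r2	0	.
chr1	26794	27200	peak0046_r2	0	.
chr1	49668	50074	peak0034_r2	0	.
chr1	71486	71904	peak0031_r2	0	.
chr1	72891	73279	peak0008_r2	0	.
chr1	100046	100457	peak0048_r2	0	.
chr1	111117	111493	peak0003_r2	0	.
chr1	130515	130922	peak0038_r2	0	.
chr1	138389	138805	peak0011_r2	0	.
chr1	143498	143894	peak0012_r2	0	.
chr1	168225	168607	peak0014_r2	0	.
chr1	181795	182174	peak0050_r2	0	.
chr1	184128	184528	noise_CHD2_D0_HET_r2_2	0	.
chr1	191520	191923	peak0029_r2	0	.
chr2	3583	3997	peak0051_r2	0	.
chr2	18846	19269	peak0002_r2	0	.
chr2	49425	49825	noise_CHD2_D0_HET_r2_0	0	.
chr2	52912	53293	peak0047_r2	0	.
chr2	61393	61798	peak0036_r2	0	.
chr2	67827	68227	peak0004_r2	0	.
chr2	76350	76764	peak0001_r2	0	.
chr2	80577	80977	noise_CHD2_D0_HET_r2_1	0	.
chr2	88745	89147	peak0030_r2	0	.
chr2	96282	96678	peak0010_r2	0	.
chr2	103334	103737	peak0037_r2	0	.
chr2	110725	111140	peak0028_r2	0	.
chr2	117784	118168	peak0049_r2	0	.
chr2	129619	130019	noise_CHD2_D0_HET_r2_3	0	.
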