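chr1	7750	8145	peak0023_r1	0	.
chr1	11865	12259	peak0022_r1	0	.
chr1	15997	16413	peak0035_r1	0	.
chr1	20995	21400	peak0007_r1	0	.
chr1	26822	27208	peak0046_r1	0	.
chr1	36357	36743	peak0027_r1	0	.
chr1	38493	38893	noise_CHD2_D35_HET_r1_1	0	.
chr1	45210	45606	peak0043_r1	0	.
chr1	55671	56081	peak0005_r1	0	.
chr1	61255	61663	peak0026_r1	0	.
chr1	72890	73279	peak0008_r1	0	.
chr1	94605	94990	peak0025_r1	0	.
chr1	100057	100457	peak0048_r1	0	.
chr1	103836	104245	peak0024_r1	0	.
chr1	111090	111501	peak0003_r1	0	.
chr1	123675	124075	noise_CHD2_D35_HET_r1_2	0	.
chr1	125757	126116	peak0039_r1	0	.
chr1	130529	130914	peak0038_r1	0	.
chr1	164668	165068	noise_CHD2_D35_HET_r1_3	0	.
chr1	181767	182212	peak0050_r1	0	.
chr2	3594	3993	peak0051_r1	0	.
chr2	18883	19269	peak0002_r1	0	.
chr2	27884	28305	peak0041_r1	0	.
chr2	41729	42155	peak0009_r1	0	.
chr2	43627	44031	peak0044_r1	0	.
chr2	48055	48440	peak0000_r1	0	.
chr2	52891	53296	peak0047_r1	0	.
chr2	61387	61777	peak0036_r1	0	.
chr2	67821	68212	peak0004_r1	0	.
chr2	94578	94992	peak0006_r1	0	.
chr2	117794	118204	peak0049_r1	0	.
chr2	129691	130091	noise_CHD2_D35_HET_r1_0	0	.
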