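chr2	47953	48553	peak0000	0	.
chr2	76245	76845	peak0001	0	.
chr2	18773	19373	peak0002	0	.
chr1	111001	111601	peak0003	0	.
chr2	67726	68326	peak0004	0	.
chr1	55569	56169	peak0005	0	.
chr2	94468	95068	peak0006	0	.
chr1	20903	21503	peak0007	0	.
chr1	72779	73379	peak0008	0	.
chr2	41637	42237	peak0009	0	.
chr1	11755	12355	peak0022	0	.
chr1	103739	104339	peak0024	0	.
chr1	94496	95096	peak0025	0	.
chr1	61150	61750	peak0026	0	.
chr1	36249	36849	peak0027	0	.
chr1	49555	50155	peak0034	0	.
chr1	15898	16498	peak0035	0	.
chr2	103238	103838	peak0037	0	.
chr1	130416	131016	peak0038	0	.
chr2	27779	28379	peak0041	0	.
chr1	45105	45705	peak0043	0	.
chr2	43534	44134	peak0044	0	.
chr1	108572	109172	peak0045	0	.
chr1	26703	27303	peak0046	0	.
chr1	99952	100552	peak0048	0	.
chr2	117680	118280	peak0049	0	.
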