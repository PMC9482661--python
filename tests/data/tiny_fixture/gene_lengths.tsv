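gene_id	length
g0000	1957
g0001	2465
g0002	3323
g0003	1764
g0004	2752
g0005	2023
g0006	2899
g0007	3629
g0008	3622
g0009	3441
g0010	3284
g0011	3670
g0012	1592
g0013	1740
g0014	3394
g0015	3822
g0016	3652
g0017	3028
g0018	3670
g0019	1880
g0020	2774
g0021	3625
g0022	1531
g0023	3650
g0024	2359
g0025	3612
g0026	3927
g0027	2009
g0028	1513
g0029	1667
g0030	2281
g0031	3733
g0032	2617
g0033	3939
g0034	2783
g0035	3079
g0036	3258
g0037	3188
g0038	2693
g0039	3958
g0040	3255
g0041	1707
g0042	3547
g0043	2084
g0044	2110
g0045	1943
g0046	3401
g0047	3034
g0048	2121
g0049	3524
g0050	2275
g0051	3639
g0052	1962
g0053	3368
g0054	2652
g0055	2725
g0056	2770
g0057	2747
g0058	1526
g0059	2255
g0060	1889
g0061	2243
g0062	2713
g0063	3934
g0064	3412
g0065	1589
g0066	3881
g0067	3629
g0068	3158
g0069	2362
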