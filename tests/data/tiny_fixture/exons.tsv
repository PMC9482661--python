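gene_id	chrom	start	end
g0000	chr1	2263	2463
g0000	chr1	2463	2663
g0000	chr1	2863	3063
g0001	chr1	5995	6895
g0001	chr1	6895	7395
g0001	chr1	7395	7695
g0002	chr1	8981	10381
g0002	chr1	10681	11581
g0002	chr1	11581	11781
g0003	chr1	14380	14880
g0003	chr1	14980	15380
g0004	chr1	18445	19145
g0004	chr1	19245	19645
g0004	chr1	19945	20145
g0004	chr1	20145	20845
g0005	chr1	23813	24613
g0005	chr1	24813	25113
g0005	chr1	25113	25313
g0006	chr1	27167	27467
g0006	chr1	27567	27867
g0006	chr1	28767	28967
g0007	chr1	31093	32293
g0007	chr1	32393	32893
g0007	chr1	33893	34293
g0008	chr1	37199	37799
g0008	chr1	37799	38199
g0008	chr1	38799	39499
g0009	chr1	41871	42171
g0009	chr1	43171	43671
g0009	chr1	43971	44871
g0010	chr1	46749	49549
g0011	chr1	51910	52210
g0011	chr1	52710	53010
g0011	chr1	53110	53310
g0011	chr1	54010	54410
g0012	chr1	56583	57083
g0013	chr1	59866	60566
g0014	chr1	62770	62970
g0014	chr1	64670	64870
g0014	chr1	64870	65270
g0014	chr1	65770	65970
g0015	chr1	68897	69097
g0015	chr1	69197	69997
g0015	chr1	70297	70597
g0016	chr1	73879	74379
g0016	chr1	74679	75279
g0017	chr1	79176	80076
g0018	chr1	84274	86674
g0019	chr1	88568	88868
g0019	chr1	88868	89768
g0019	chr1	89768	89968
g0019	chr1	90068	90268
g0020	chr1	92197	92397
g0020	chr1	93297	93497
g0020	chr1	93497	94397
g0021	chr1	97036	97636
g0021	chr1	97936	98736
g0022	chr1	102642	103042
g0022	chr1	103442	103942
g0023	chr1	105352	105952
g0023	chr1	106152	106452
g0023	chr1	106452	106752
g0023	chr1	107552	107852
g0024	chr1	111442	112342
g0024	chr1	112342	113142
g0025	chr1	115022	115222
g0025	chr1	116022	116322
g0025	chr1	116722	117222
g0025	chr1	117422	117822
g0026	chr1	122613	124113
g0027	chr1	126054	126654
g0027	chr1	126654	127054
g0027	chr1	127054	127854
g0028	chr1	129835	130735
g0029	chr1	132421	132821
g0029	chr1	132821	133121
g0029	chr1	133121	133321
g0029	chr1	133421	133821
g0030	chr1	136335	137535
g0031	chr1	140229	141029
g0031	chr1	141329	142329
g0031	chr1	142629	143129
g0032	chr1	145361	147461
g0033	chr1	150217	152017
g0034	chr1	154520	154720
g0034	chr1	156620	156820
g0035	chr1	158492	158692
g0035	chr1	158792	159392
g0035	chr1	159492	159892
g0035	chr1	160492	160992
g0036	chr1	163302	163802
g0036	chr1	164002	164702
g0036	chr1	164802	165302
g0036	chr1	165602	165902
g0037	chr1	168386	168586
g0037	chr1	168986	169186
g0037	chr1	169186	170586
g0037	chr1	170686	170886
g0038	chr1	173218	174318
g0038	chr1	174818	175118
g0039	chr1	178650	179350
g0040	chr1	183299	183499
g0040	chr1	183499	183899
g0040	chr1	183899	184299
g0040	chr1	185099	186099
g0041	chr1	188388	189088
g0041	chr1	189588	189888
g0042	chr1	192810	193210
g0042	chr1	193410	194710
g0043	chr2	2450	3050
g0044	chr2	5292	6492
g0044	chr2	6792	6992
g0045	chr2	9027	9327
g0046	chr2	11509	11809
g0046	chr2	12309	12509
g0046	chr2	12509	13109
g0046	chr2	13309	14709
g0047	chr2	16012	16412
g0047	chr2	16412	16912
g0047	chr2	17912	18512
g0048	chr2	20395	21195
g0048	chr2	21295	21995
g0049	chr2	24933	27033
g0050	chr2	31232	31732
g0051	chr2	36683	37783
g0052	chr2	39964	40364
g0052	chr2	40664	41064
g0052	chr2	41164	41764
g0053	chr2	44099	45499
g0053	chr2	46099	46799
g0054	chr2	48388	50188
g0055	chr2	53265	53965
g0055	chr2	54765	55265
g0056	chr2	57986	58386
g0057	chr2	61777	62377
g0057	chr2	63177	64077
g0058	chr2	66892	67692
g0058	chr2	67792	67992
g0059	chr2	70506	70706
g0059	chr2	71006	71506
g0059	chr2	71506	71906
g0060	chr2	74771	75771
g0061	chr2	78695	78895
g0061	chr2	78895	79195
g0062	chr2	81353	81853
g0062	chr2	81953	82453
g0062	chr2	82453	82753
g0062	chr2	83253	83653
g0063	chr2	85731	85931
g0063	chr2	85931	86131
g0063	chr2	86931	88231
g0063	chr2	88731	88931
g0064	chr2	91326	91626
g0064	chr2	92226	92826
g0064	chr2	93026	93326
g0064	chr2	93626	94126
g0065	chr2	96491	96691
g0065	chr2	96791	97391
g0065	chr2	97391	97591
g0065	chr2	97691	97891
g0066	chr2	100501	100901
g0066	chr2	100901	101301
g0066	chr2	101301	102501
g0066	chr2	102801	103001
g0067	chr2	106561	108761
g0068	chr2	112070	113170
g0069	chr2	115591	116391
g0069	chr2	116491	116691
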