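gene_id	chrom	start	end	strand
g0000	chr1	1963	3920	-
g0001	chr1	5395	7860	-
g0002	chr1	8881	12204	-
g0003	chr1	14380	16144	-
g0004	chr1	18345	21097	-
g0005	chr1	23413	25436	-
g0006	chr1	26967	29866	+
g0007	chr1	30993	34622	-
g0008	chr1	36399	40021	+
g0009	chr1	41871	45312	-
g0010	chr1	46449	49733	-
g0011	chr1	51010	54680	-
g0012	chr1	55783	57375	+
g0013	chr1	59766	61506	-
g0014	chr1	62770	66164	+
g0015	chr1	67797	71619	-
g0016	chr1	72979	76631	+
g0017	chr1	78176	81204	+
g0018	chr1	83474	87144	-
g0019	chr1	88568	90448	-
g0020	chr1	92097	94871	-
g0021	chr1	96536	100161	-
g0022	chr1	102642	104173	-
g0023	chr1	105352	109002	-
g0024	chr1	111342	113701	+
g0025	chr1	114722	118334	-
g0026	chr1	120713	124640	+
g0027	chr1	126054	128063	+
g0028	chr1	129335	130848	-
g0029	chr1	132421	134088	+
g0030	chr1	136335	138616	-
g0031	chr1	139829	143562	-
g0032	chr1	145161	147778	+
g0033	chr1	148817	152756	-
g0034	chr1	154420	157203	-
g0035	chr1	158492	161571	-
g0036	chr1	163102	166360	+
g0037	chr1	168386	171574	+
g0038	chr1	173018	175711	-
g0039	chr1	177950	181908	-
g0040	chr1	183099	186354	-
g0041	chr1	188288	189995	+
g0042	chr1	191610	195157	+
g0043	chr2	1750	3834	-
g0044	chr2	5292	7402	+
g0045	chr2	8427	10370	+
g0046	chr2	11409	14810	-
g0047	chr2	16012	19046	-
g0048	chr2	20395	22516	+
g0049	chr2	24633	28157	-
g0050	chr2	30432	32707	+
g0051	chr2	34883	38522	-
g0052	chr2	39964	41926	-
g0053	chr2	43799	47167	+
g0054	chr2	48288	50940	+
g0055	chr2	53065	55790	+
g0056	chr2	57186	59956	-
g0057	chr2	61677	64424	+
g0058	chr2	66592	68118	-
g0059	chr2	69906	72161	+
g0060	chr2	74571	76460	-
g0061	chr2	77495	79738	+
g0062	chr2	81053	83766	+
g0063	chr2	85131	89065	-
g0064	chr2	91326	94738	-
g0065	chr2	96491	98080	+
g0066	chr2	99601	103482	-
g0067	chr2	105561	109190	-
g0068	chr2	110970	114128	+
g0069	chr2	115591	117953	-
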