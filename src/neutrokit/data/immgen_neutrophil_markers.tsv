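gene_id	BM	BL	SF	UA	TG	nf_median	nf_min	nf_max	non_nf_median	non_nf_min	non_nf_max	non_nf_above_120
1100001G20Rik	3506	2490	980	1064	1279	1279	980	3506	92	64	376	12
2010002M12Rik	262	143	152	164	146	152	143	262	16	11	38	0
9830107B12Rik	1028	518	230	396	724	518	230	1028	20	14	63	0
Ankrd22	2569	1065	766	641	828	828	641	2569	41	27	153	2
Arg2	1345	1641	1732	1606	1810	1641	1345	1810	40	27	316	5
Ceacam10	1489	542	247	253	168	253	168	1489	30	22	116	0
Chi3l1	7201	4700	2612	3346	6669	4700	2612	7201	49	35	549	9
Clec5a	3264	1979	1966	1908	3421	1980	1908	3421	24	15	797	33
Csf3r	3146	5917	3274	6041	5337	5337	3146	6041	37	23	1068	40
Cxcr2	3777	4194	3476	4324	3799	3799	3476	4324	15	12	466	5
Dhrs9	1522	1795	1113	1763	1594	1594	1113	1795	28	19	420	8
Fam123a	283	259	310	207	122	259	122	310	49	32	93	0
Gm9949	210	314	154	400	231	231	154	400	54	36	106	0
Grina	5809	7197	7489	8429	7112	7197	5809	8429	533	184	2205	198
Il1f9	3836	4955	3896	6662	8800	4955	3836	8800	19	14	262	3
Kctd11	126	140	121	137	180	137	121	180	58	42	109	0
Mgam	1389	982	256	247	294	294	247	1389	32	23	112	0
Mir29c	218	186	155	614	537	218	155	614	28	13	113	0
Mrgpra2a	2605	1103	1856	697	2200	1856	697	2605	41	27	213	4
Mrgpra2b	2279	950	1589	568	1949	1589	568	2279	41	29	194	3
Ppp1r3d	788	1018	719	1091	645	788	645	1091	133	93	280	143
Prrg2	137	181	155	152	155	155	137	181	63	46	108	0
Rlf	1213	1083	1031	1268	1315	1213	1031	1315	344	80	513	195
Rnf11	1139	1193	1390	1036	931	1139	931	1390	248	114	451	197
S100a7a	148	154	128	235	199	154	128	235	84	67	116	0
Sfxn5	915	1308	885	2129	1671	1308	885	2129	75	47	269	19
Sgms2	1580	1060	2172	1352	1890	1580	1060	2172	40	26	374	8
Slc22a20	138	139	149	137	136	138	136	149	77	50	107	0
Slfn4	5074	4516	3032	9288	11010	5074	3032	11010	42	31	1455	11
Spatc1	2020	2748	3598	2597	2640	2640	2020	3598	32	22	119	0
Stfa2l1	1270	3317	3750	2409	2120	2409	1270	3750	10	8	107	0
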