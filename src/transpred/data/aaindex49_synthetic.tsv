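property	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
SYN01	0.6383	0.7286	0.6132	0.0916	0.6769	0.9955	1.0000	0.4025	0.0342	0.3244	0.1607	0.6986	0.5854	0.3001	0.0000	0.3077	0.3779	0.7650	0.7189	0.5039
SYN02	0.0923	0.7158	0.3596	0.8425	0.1321	0.3211	0.4302	0.4349	0.0000	0.0059	0.1615	0.8020	0.5165	1.0000	0.4733	0.6192	0.8740	0.5925	0.7242	0.5360
SYN03	0.6667	0.1118	0.2765	0.6193	0.8390	0.1901	0.0564	0.0401	0.0410	0.3907	0.4887	0.0000	0.5096	0.2440	1.0000	0.3978	0.6294	0.4795	0.7752	0.0031
SYN04	0.0813	0.4475	0.3208	0.7887	0.9749	0.0000	0.7367	0.3811	0.6589	0.8147	0.6204	0.2143	0.2632	0.9711	0.3779	0.8978	0.9021	0.6654	1.0000	0.9557
SYN05	0.0659	0.0000	0.5716	0.6436	0.7527	1.0000	0.8347	0.8661	0.8531	0.7442	0.2752	0.7568	0.4319	0.7781	0.1992	0.9658	0.0352	0.9688	0.3796	0.8137
SYN06	0.5358	0.9375	0.0000	0.2940	0.0356	0.2453	0.4944	0.2684	1.0000	0.6435	0.7385	0.5585	0.6634	0.3554	0.7569	0.4251	0.3461	0.3375	0.6038	0.4660
SYN07	0.9928	0.9021	0.1209	0.2202	0.6194	0.5000	0.5849	0.9861	0.7789	0.1742	0.7463	0.8446	0.0213	0.5918	0.3102	0.0000	1.0000	0.2239	0.2679	0.7610
SYN08	0.4400	0.7551	0.6236	0.1017	0.1810	0.2024	0.9157	0.0489	0.6462	0.0000	0.1455	0.0212	0.8871	0.7724	1.0000	0.9600	0.4161	0.9289	0.9897	0.3462
SYN09	0.7887	0.6738	0.6587	1.0000	0.9731	0.1439	0.8796	0.6933	0.0511	0.7934	0.5127	0.5154	0.7954	0.4871	0.0000	0.1429	0.4736	0.5176	0.6808	0.9722
SYN10	0.5235	0.2014	0.3454	0.9741	0.9927	0.1040	0.6052	0.6247	0.0000	0.3295	0.8706	1.0000	0.2702	0.2044	0.3917	0.6470	0.0415	0.2285	0.8234	0.0537
SYN11	0.5066	0.9889	0.7075	0.0265	0.5910	0.1988	0.4242	0.5818	0.8753	0.2041	0.7232	0.9353	0.1167	0.1750	0.7592	0.5876	0.7894	1.0000	0.0000	0.9432
SYN12	0.2271	0.1665	0.7433	0.9749	0.8603	0.5507	1.0000	0.1851	0.7354	0.6713	0.5543	0.8951	0.3093	0.5908	0.0000	0.1310	0.1133	0.3336	0.5180	0.6578
SYN13	0.0000	0.8689	0.8473	0.5619	0.0184	0.7323	0.7915	0.3716	0.9068	1.0000	0.2146	0.9514	0.6793	0.0659	0.9488	0.2282	0.6445	0.0378	0.3262	0.0465
SYN14	0.5492	0.8789	0.7882	0.2562	0.8263	0.7864	0.7391	0.5129	0.6041	0.9860	0.7451	0.0054	0.0000	0.9864	0.5858	0.9201	0.7438	0.8269	1.0000	0.4598
SYN15	0.2602	0.0310	1.0000	0.8753	0.6277	0.7188	0.4481	0.8775	0.3419	0.8632	0.3833	0.1597	0.6965	0.0000	0.3552	0.5082	0.3861	0.0454	0.5145	0.3791
SYN16	0.9658	0.3497	0.1832	0.7187	0.7350	0.4736	0.6884	0.0253	0.2646	0.7431	0.8777	0.2740	0.9607	0.0234	0.0000	0.9545	0.5176	1.0000	0.2025	0.9125
SYN17	0.2448	0.4351	0.7548	0.9461	0.0000	1.0000	0.0706	0.2013	0.2959	0.7968	0.4970	0.2441	0.6711	0.0769	0.5724	0.4083	0.7960	0.3399	0.5046	0.7172
SYN18	0.0298	0.0160	0.7602	0.7568	0.3070	0.5448	0.1672	0.2679	0.2410	1.0000	0.4146	0.7033	0.3171	0.6353	0.9459	0.4166	0.0000	0.0962	0.3801	0.6842
SYN19	0.0000	0.6014	0.4513	0.8765	0.2208	0.0944	0.9057	0.2373	0.5356	0.5532	0.7546	0.8707	0.9482	0.9413	0.7252	0.6852	0.4245	0.8424	1.0000	0.8387
SYN20	0.6701	0.2724	0.0041	0.5006	0.5093	0.3616	0.1766	0.0000	0.6831	0.8215	0.4994	0.3222	0.9993	0.8598	0.6620	0.0897	0.1263	1.0000	0.3893	0.8976
SYN21	0.5341	0.7993	0.4968	0.5470	0.1304	0.1969	0.4843	0.2208	1.0000	0.9951	0.4430	0.6735	0.8570	0.2373	0.2571	0.2827	0.0000	0.6151	0.1110	0.8286
SYN22	0.4516	0.6715	0.1861	0.9017	0.1148	0.7953	0.1296	0.7224	0.9132	0.0000	0.7335	0.9148	0.7078	0.3657	0.7219	0.7345	0.5908	0.1587	0.5774	1.0000
SYN23	0.3410	0.6534	0.0000	0.1928	0.1491	0.6756	0.6219	0.3385	0.8017	0.1571	0.5185	1.0000	0.3679	0.9597	0.4603	0.9157	0.6044	0.1404	0.1039	0.6790
SYN24	0.0695	0.6998	0.4326	0.0000	0.8027	0.0324	0.4565	0.3279	0.4893	1.0000	0.4011	0.0398	0.7175	0.4798	0.4040	0.1660	0.4543	0.0270	0.4744	0.7849
SYN25	0.7958	0.9613	0.4542	0.2975	0.3225	0.3440	0.3125	0.9610	0.5882	0.1690	1.0000	0.2755	0.7555	0.8398	0.9284	0.0000	0.9513	0.6362	0.3821	0.4169
SYN26	0.5138	0.5207	0.1774	0.9028	0.3314	0.1922	0.9879	0.3336	0.5610	0.1754	0.4260	1.0000	0.8248	0.2768	0.2589	0.5392	0.7920	0.7688	0.0000	0.9064
SYN27	0.0371	0.9392	0.0316	0.7089	0.6087	0.2977	0.1838	0.6705	0.2025	0.7938	0.4389	0.1711	0.8726	0.6643	1.0000	0.0000	0.4836	0.3395	0.5063	0.6988
SYN28	0.5848	1.0000	0.6258	0.5215	0.2548	0.8587	0.1508	0.8182	0.0445	0.0000	0.7187	0.8169	0.6376	0.1040	0.2878	0.7755	0.2068	0.2605	0.1461	0.9523
SYN29	0.7160	0.6413	1.0000	0.8093	0.4119	0.2668	0.9727	0.1693	0.0000	0.7857	0.9421	0.7782	0.9569	0.9891	0.8621	0.6576	0.6999	0.5491	0.1320	0.2957
SYN30	0.6922	0.3547	0.2086	0.6518	0.8822	0.0339	0.2594	0.1697	1.0000	0.7304	0.8013	0.5135	0.4546	0.0421	0.0604	0.7221	0.9187	0.4812	0.0000	0.6735
SYN31	0.4798	0.5643	0.2046	0.8125	0.0872	0.4036	0.7798	0.4364	0.0271	1.0000	0.8098	0.3128	0.7890	0.2177	0.1342	0.5522	0.8122	0.0000	0.9883	0.7575
SYN32	0.6348	0.3619	0.1067	0.4768	0.0071	0.0000	0.2635	0.7738	0.4859	0.7147	0.0373	0.3259	0.6744	0.5236	0.5560	1.0000	0.5642	0.7185	0.6757	0.5082
SYN33	1.0000	0.4435	0.8171	0.2143	0.6440	0.4528	0.4192	0.6452	0.0557	0.4369	0.6808	0.5192	0.5836	0.8672	0.0000	0.2667	0.1027	0.3768	0.4172	0.7973
SYN34	0.0499	0.7222	0.6258	0.0000	0.1779	0.3887	0.4367	0.4708	0.3299	0.4062	0.4300	0.1752	0.9890	0.9503	0.0024	0.6641	1.0000	0.1313	0.6780	0.0381
SYN35	0.3492	0.4199	0.0453	0.3569	0.7227	1.0000	0.5529	0.2116	0.3468	0.1679	0.2389	0.7436	0.4787	0.4187	0.2573	0.9904	0.4674	0.4023	0.5404	0.0000
SYN36	0.0975	0.2464	1.0000	0.4440	0.3461	0.5098	0.2440	0.7377	0.3985	0.0610	0.4481	0.0344	0.3855	0.0143	0.5592	0.2330	0.3760	0.0000	0.2416	0.7372
SYN37	0.0682	0.1522	0.4125	1.0000	0.7387	0.0721	0.2361	0.7587	0.0215	0.0354	0.4312	0.3211	0.4653	0.8914	0.0000	0.3427	0.4966	0.4395	0.3515	0.4523
SYN38	0.4008	0.3587	0.4898	0.0000	0.3238	0.0952	0.2607	0.6310	0.6050	0.0623	0.4407	0.9424	0.2874	0.0925	0.0798	0.6529	0.8345	0.2314	0.1569	1.0000
SYN39	1.0000	0.0523	0.2493	0.5218	0.5688	0.4815	0.0769	0.2684	0.1206	0.8402	0.1337	0.1303	0.5908	0.6952	0.9337	0.8446	0.9215	0.7350	0.0000	0.1745
SYN40	0.2028	0.5174	0.5942	0.7042	1.0000	0.4453	0.1587	0.9911	0.6317	0.8733	0.9823	0.4304	0.6070	0.4661	0.7986	0.3446	0.8729	0.0000	0.8439	0.2590
SYN41	0.0455	0.2013	0.9740	0.6357	0.4643	0.5389	0.2839	0.0217	0.7317	0.4417	0.3230	0.3102	0.2186	1.0000	0.8173	0.8134	0.8092	0.9965	0.4995	0.0000
SYN42	0.1075	0.3962	0.0760	0.7155	0.8739	0.6573	0.1668	0.9934	1.0000	0.8119	0.1329	0.7068	0.8786	0.7341	0.9514	0.8149	0.2761	0.0000	0.2733	0.2206
SYN43	0.9601	0.6695	0.6888	0.9597	0.6608	0.6246	1.0000	0.4680	0.4053	0.8206	0.3431	0.8663	0.6184	0.0000	0.6346	0.4301	0.0937	0.0698	0.0070	0.9802
SYN44	0.0830	0.3573	0.7299	0.3705	0.5392	0.0304	1.0000	0.1177	0.1120	0.8645	0.0817	0.4919	0.6394	0.0000	0.9511	0.3914	0.4970	0.6544	0.4712	0.9691
SYN45	0.5093	0.5577	0.0000	0.6361	0.5013	0.2830	0.9943	0.5761	0.9648	0.3110	0.3337	0.7812	0.9413	0.2277	0.3074	0.9808	0.6336	0.2307	1.0000	0.5988
SYN46	0.0037	0.0934	0.0000	0.3819	0.7914	0.0972	0.7274	0.7235	0.6695	0.1716	0.5600	0.9940	0.8718	0.2330	0.9732	0.8280	0.8887	1.0000	0.4098	0.6861
SYN47	0.1998	0.7974	0.4333	0.1636	0.4142	0.7427	0.0624	0.0667	0.1417	0.3981	0.0000	0.5780	0.1527	0.3149	0.4962	0.7247	0.6797	0.5560	0.8549	1.0000
SYN48	0.8160	0.9036	0.9593	0.9465	0.4846	0.1056	0.0000	0.8553	0.8411	0.8972	0.6267	0.6606	0.6022	0.1216	0.9075	1.0000	0.6469	0.4434	0.3548	0.6308
SYN49	0.2939	0.3338	0.6497	0.9306	0.8172	0.4843	0.2331	0.4013	0.2483	0.0932	1.0000	0.9766	0.0000	0.1216	0.8584	0.4011	0.3042	0.0870	0.0614	0.7274
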