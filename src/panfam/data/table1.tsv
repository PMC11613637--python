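Name	Gene	Chr	Start	End	Strand	AA	MW	Ip	II	AI	GRAVY	Subcellular Localization
Xzs4_CBF1	EVM0000338	Chr3	33884102	33884695	+	197	21797.67	4.609949	61.38325	61.92893	-0.56193	Cytoplasm
Xzs4_CBF2	EVM0012620	Chr4	16342842	16343498	-	218	23888.79	5.487373	66.07523	70.73394	-0.28165	Nucleus
Xzs4_CBF3	EVM0005981	Chr11	25619969	25620652	-	227	25142.81	5.037265	59.7696	73.17181	-0.52775	Nucleus
Xzs4_CBF4	EVM0005738	Chr11	25623384	25624058	-	224	24934.69	5.116726	55.4683	71.96429	-0.48705	Nucleus
Xzs4_CBF5	EVM0002591	Chr11	25633381	25634664	-	205	22749.5	7.712903	59.06829	78.09756	-0.47463	Nucleus
Xzs4_CBF6	EVM0002707	Chr11	25646290	25652327	-	234	26220.24	5.495103	51.77949	73.11966	-0.50641	Nucleus
Xzs4_CBF7	EVM0017184	Chr11	25660715	25661398	-	227	25016.87	5.027489	45.62555	78.32599	-0.38899	Nucleus
Xzs4_CBF8	EVM0002147	Chr11	25675706	25676392	-	228	24710.24	5.147646	49.74474	66.84211	-0.62632	Mitochondria
Xzs4_CBF9	EVM0004174	Chr12	23889386	23890914	-	224	25153.27	6.245491	50.04464	62.90179	-0.49643	Nucleus
Xzs4_CBF10	EVM0001246	Chr12	23906031	23906546	-	171	18407.26	5.207327	61.58596	61.75439	-0.58304	Mitochondria
Xzs4_CBF11	EVM0016628	Chr13	27523812	27524471	+	219	24181.49	7.743199	71.98539	54.47489	-0.81963	Nucleus
Xzs4_CBF12	EVM0007008	Chr13	27539028	27540486	+	235	26400.48	9.704506	58.72553	58.25532	-0.79149	Nucleus
Xzs4_CBF13	EVM0017076	Chr13	27586709	27587323	-	204	21778.91	5.393645	56.3902	70.04902	-0.39461	Chloroplast
Xwf8_CBF1	XS01G00649	Chr1	6557308	6563676	-	505	56596.05	6.054569	51.46099	69.16832	-0.59624	Nucleus
Xwf8_CBF2	XS02G10797	Chr2	33824715	33825698	+	197	21811.7	4.609949	59.04518	61.92893	-0.56142	Cytoplasm
Xwf8_CBF3	XS10G03018	Chr10	4927963	4929265	+	219	23384.77	5.138666	70.43881	61.55251	-0.61918	Nucleus
Xwf8_CBF4	XS10G03020	Chr10	4945033	4946017	+	237	26075.87	4.84117	52.68819	61.51899	-0.46751	Nucleus
Xwf8_CBF5	XS13G06172	Chr13	1326350	1327638	+	228	24710.24	5.147646	49.74474	66.84211	-0.62632	Mitochondria
Xwf8_CBF6	XS13G06174	Chr13	1351200	1352622	+	303	33773.14	8.268086	50.28581	87.32673	-0.27393	Chloroplast
Xwf8_CBF7	XS13G06177	Chr13	1377680	1378360	+	226	25035.84	5.332941	55.86327	74.29204	-0.4677	Nucleus
Xwf8_CBF8	XS13G06178	Chr13	1385326	1389570	+	227	25309.01	4.972127	60.29427	70.57269	-0.57225	Nucleus
Xjg_CBF1	XS07G0175500	Chr7	16676325	16676981	+	218	23888.79	5.487373	66.07523	70.73394	-0.28165	Nucleus
Xjg_CBF2	XS11G0182400	Chr11	22646316	22647029	-	237	26075.87	4.84117	52.68819	61.51899	-0.46751	Nucleus
Xjg_CBF3	XS11G0182700	Chr11	22661982	22662641	-	219	23384.77	5.138666	70.43881	61.55251	-0.61918	Nucleus
Xjg_CBF4	XS12G0008300	Chr12	766416	768911	+	314	35522.79	5.404104	68.11656	50.41401	-0.96369	Nucleus
Xjg_CBF5	XS12G0009400	Chr12	836129	836746	-	205	21851.96	5.393645	59.58439	69.70732	-0.39707	Chloroplast
Xjg_CBF6	XS13G0038500	Chr13	3422471	3423674	+	236	25783.72	6.438005	50.03559	66.65254	-0.56059	Mitochondria
Xjg_CBF7	XS13G0038700	Chr13	3438704	3439387	+	227	24959.82	5.205622	46.07797	76.60793	-0.41233	Nucleus
Xjg_CBF8	XS13G0039000	Chr13	3453599	3459713	+	200	22171.83	5.740761	61.87505	74.8	-0.4285	Nucleus
Xjg_CBF9	XS13G0039200	Chr13	3478296	3478976	+	226	25035.84	5.332941	55.86327	74.29204	-0.4677	Nucleus
Xjg_CBF10	XS13G0039300	Chr13	3488280	3488954	+	224	24934.69	5.116726	55.4683	71.96429	-0.48705	Nucleus
Xjg_CBF11	XS13G0039400	Chr13	3491642	3492325	+	227	25170.87	5.128264	57.74053	73.17181	-0.53216	Nucleus
Xg11_CBF1	Xso_Chr02_02907	Chr2	33907198	33907791	+	197	22264.22	4.931487	65.62462	57.38693	-0.64221	Cytoplasm
Xg11_CBF2	Xso_Chr05_01501	Chr5	17498843	17499499	+	218	24341.31	6.819338	71.83318	66.54545	-0.35727	Nucleus
Xg11_CBF3	Xso_Chr10_00492	Chr10	6812419	6813078	+	219	23765.23	6.313812	71.92443	57.46606	-0.67738	Nucleus
Xg11_CBF4	Xso_Chr10_00493	Chr10	6828202	6828915	+	237	26528.39	5.110701	55.76946	57.74059	-0.53556	Nucleus
Xg11_CBF5	Xso_Chr13_00407	Chr13	3346447	3347133	+	228	25286.15	5.317026	49.24254	74.5614	-0.46447	Nucleus
Xg11_CBF6	Xso_Chr13_00408	Chr13	3361997	3362680	+	227	34117.71	8.675204	46.52724	82.98077	-0.20321	Nucleus
Xg11_CBF7	Xso_Chr13_00409	Chr13	3372979	3374580	+	309	30067.93	7.101373	53.87406	81.50376	-0.25301	Chloroplast
Xg11_CBF8	Xso_Chr13_00410	Chr13	3383274	3384065	+	263	25160.94	5.304806	56.544	69.91111	-0.52311	Nucleus
Xg11_CBF9	Xso_Chr13_00412	Chr13	3396403	3397083	+	226	25369.07	5.21483	60.81228	71.14035	-0.56316	Nucleus
Xg11_CBF10	Xso_Chr13_00414	Chr13	3404138	3404812	+	224	25337.21	5.740875	59.1022	70.52863	-0.52203	Nucleus
Xg11_CBF11	Xso_Chr13_00415	Chr13	3408292	3408975	+	227	24936.5	5.428715	50.82664	64.84716	-0.66114	Nucleus
Xg11_CBF12	Xso_Chr14_02233	Chr14	27536596	27537210	+	204	22217.4	5.890532	63.93204	65.58252	-0.47476	Mitochondria
Xg11_CBF13	Xso_Chr14_02238	Chr14	27565703	27566766	-	279	31885.36	8.291811	58.17107	65.57143	-0.71214	Nucleus
Xg11_CBF14	Xso_Chr14_02243	Chr14	27589481	27590146	-	221	24506.94	7.749508	70.19457	52.66968	-0.78145	Nucleus
Xg11_CBF15	Xso_Chr14_02247	Chr14	27604677	27605342	-	221	24712.2	8.413011	72.99865	53.73874	-0.80541	Nucleus
Xzg2_CBF1	Xsorbifolium007924.1	Chr5	2507676	2508787	-	197	21811.7	4.609949	59.04518	61.92893	-0.56142	Cytoplasm
Xzg2_CBF2	Xsorbifolium011078.1	Chr6	16943261	16944430	+	218	23874.76	5.487373	66.95872	70.27523	-0.27982	Nucleus
Xzg2_CBF3	Xsorbifolium017345.1	Chr10	26777559	26778886	-	237	26119.88	4.790697	52.05401	61.09705	-0.48987	Nucleus
Xzg2_CBF4	Xsorbifolium017346.1	Chr10	26793571	26795196	-	171	18407.26	5.207327	61.58596	61.75439	-0.58304	Mitochondria
Xzg2_CBF5	Xsorbifolium018921.1	Chr12	766480	767209	+	221	24485.94	7.743199	71.98281	55.74661	-0.77014	Nucleus
Xzg2_CBF6	Xsorbifolium018924.1	Chr12	786421	787070	+	205	22648.73	6.20866	73.00244	49.12195	-0.86195	Nucleus
Xzg2_CBF7	Xsorbifolium018934.1	Chr12	848979	849593	-	204	21764.88	5.393645	58.88333	70.04902	-0.3951	Mitochondria
Xzg2_CBF8	Xsorbifolium020780.1	Chr13	3623971	3625226	+	228	24710.24	5.147646	49.74474	66.84211	-0.62632	Mitochondria
Xzg2_CBF9	Xsorbifolium020781.1	Chr13	3640044	3641082	+	227	24844.64	5.101436	43.42775	74.88987	-0.41806	Nucleus
Xzg2_CBF10	Xsorbifolium020782.1	Chr13	3649784	3650467	+	227	25252.03	5.324586	50.66872	76.1674	-0.47357	Nucleus
Xzg2_CBF11	Xsorbifolium020785.1	Chr13	3674063	3674959	+	226	25035.84	5.332941	55.86327	74.29204	-0.4677	Nucleus
Xzg2_CBF12	Xsorbifolium020786.1	Chr13	3683915	3688390	+	227	25309.01	4.972127	60.29427	70.57269	-0.57225	Nucleus
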