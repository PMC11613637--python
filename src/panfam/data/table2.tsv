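Gene 1	Gene 2	Ka	Ks	Ka/Ks	Time (MYA)	Duplication Type
Xzs4_CBF3	Xzs4_CBF4	0.0395	0.0541	0.73	1.80	Tandem
Xzs4_CBF3	Xzs4_CBF5	0.0464	0.0536	0.87	1.79	Tandem
Xzs4_CBF3	Xzs4_CBF6	0.0628	0.1152	0.55	3.84	Tandem
Xzs4_CBF3	Xzs4_CBF7	0.0294	0.0768	0.38	2.56	Tandem
Xzs4_CBF4	Xzs4_CBF5	0.0262	0.0421	0.62	1.40	Tandem
Xzs4_CBF4	Xzs4_CBF6	0.0656	0.0931	0.70	3.10	Tandem
Xzs4_CBF4	Xzs4_CBF7	0.0396	0.076	0.52	2.53	Tandem
Xzs4_CBF5	Xzs4_CBF6	0.077	0.126	0.61	4.20	Tandem
Xzs4_CBF5	Xzs4_CBF7	0.05	0.0753	0.66	2.51	Tandem
Xzs4_CBF6	Xzs4_CBF7	0.0662	0.1522	0.43	5.07	Tandem
Xzs4_CBF11	Xzs4_CBF12	0.0331	0.0204	1.62	0.68	Tandem
Xwf8_CBF6	Xwf8_CBF7	0.0417	0.0868	0.48	2.89	Tandem
Xwf8_CBF6	Xwf8_CBF8	0.0389	0.0973	0.40	3.24	Tandem
Xwf8_CBF7	Xwf8_CBF8	0.0497	0.0692	0.72	2.31	Tandem
Xjg_CBF7	Xjg_CBF8	0.0544	0.1124	0.48	3.75	Tandem
Xjg_CBF7	Xjg_CBF9	0.0486	0.0821	0.59	2.74	Tandem
Xjg_CBF7	Xjg_CBF10	0.0514	0.0731	0.70	2.44	Tandem
Xjg_CBF7	Xjg_CBF11	0.0253	0.0825	0.31	2.75	Tandem
Xjg_CBF8	Xjg_CBF9	0.0544	0.0825	0.66	2.75	Tandem
Xjg_CBF8	Xjg_CBF10	0.0455	0.0831	0.55	2.77	Tandem
Xjg_CBF8	Xjg_CBF11	0.0544	0.0732	0.74	2.44	Tandem
Xjg_CBF9	Xjg_CBF10	0.0397	0.0356	1.12	1.19	Tandem
Xjg_CBF9	Xjg_CBF11	0.0456	0.0446	1.02	1.49	Tandem
Xg11_CBF6	Xg11_CBF7	0.048	0.0332	1.45	1.11	Tandem
Xg11_CBF6	Xg11_CBF8	0.0615	0.0716	0.86	2.39	Tandem
Xg11_CBF6	Xg11_CBF9	0.0595	0.0421	1.41	1.40	Tandem
Xg11_CBF6	Xg11_CBF10	0.0639	0.0555	1.15	1.85	Tandem
Xg11_CBF6	Xg11_CBF11	0.0422	0.0332	1.27	1.11	Tandem
Xg11_CBF8	Xg11_CBF9	0.0583	0.0634	0.92	2.11	Tandem
Xg11_CBF8	Xg11_CBF10	0.0695	0.0385	1.81	1.28	Tandem
Xg11_CBF8	Xg11_CBF11	0.0644	0.0717	0.90	2.39	Tandem
Xg11_CBF9	Xg11_CBF10	0.0519	0.0298	1.74	0.99	Tandem
Xg11_CBF9	Xg11_CBF11	0.0536	0.0422	1.27	1.41	Tandem
Xg11_CBF10	Xg11_CBF11	0.055	0.0557	0.99	1.86	Tandem
Xg11_CBF13	Xg11_CBF14	0.0528	0.0273	1.93	0.91	Tandem
Xg11_CBF13	Xg11_CBF15	0.0383	0.0273	1.40	0.91	Tandem
Xg11_CBF14	Xg11_CBF15	0.0192	0.0168	1.14	0.56	Tandem
Xzg2_CBF5	Xzg2_CBF6	0.0162	0.0105	1.54	0.35	Tandem
Xzg2_CBF9	Xzg2_CBF10	0.0361	0.1502	0.24	5.01	Tandem
Xzg2_CBF9	Xzg2_CBF11	0.053	0.0891	0.59	2.97	Tandem
Xzg2_CBF9	Xzg2_CBF12	0.0393	0.0779	0.50	2.60	Tandem
Xzg2_CBF10	Xzg2_CBF11	0.0393	0.1014	0.39	3.38	Tandem
Xzg2_CBF10	Xzg2_CBF12	0.0426	0.0901	0.47	3.00	Tandem
Xzg2_CBF11	Xzg2_CBF12	0.046	0.0326	1.41	1.09	Tandem
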