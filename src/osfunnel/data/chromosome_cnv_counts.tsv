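chromosome	total_genes	significant_genes	significant_pct	cnv_gain_count	cnv_loss_count	p_value	odds_ratio	neg_log_p
1	2652	220	8.30	58	205	0.997	0.800	0.003
2	1728	56	3.24	16	56	1.000	0.287	0.000
3	1477	60	4.06	18	60	1.000	0.368	0.000
4	1011	88	8.70	47	82	0.813	0.856	0.207
5	1216	26	2.14	9	26	1.000	0.189	0.000
6	1374	21	1.53	15	21	1.000	0.133	0.000
7	1269	10	0.79	6	10	1.000	0.068	0.000
8	962	261	27.13	188	160	1.05e-72	3.617	165.736
9	1063	132	12.42	41	132	7.75e-03	1.294	4.860
10	1061	367	34.59	8	367	1.44e-163	5.375	374.960
11	1609	428	26.60	129	428	3.13e-116	3.705	265.958
12	1326	127	9.58	116	127	0.344	0.954	1.067
13	601	6	1.00	2	6	1.000	0.089	0.000
14	876	12	1.37	11	2	1.000	0.121	0.000
15	931	193	20.73	81	191	1.33e-28	2.467	64.185
16	1086	280	25.78	7	278	4.18e-70	3.386	159.750
17	1498	207	13.82	70	205	4.02e-7	1.485	14.728
18	407	12	2.95	2	12	1.000	0.271	0.000
19	1725	108	6.26	77	108	1.000	0.586	0.000
20	749	10	1.34	6	10	1.000	0.119	0.000
21	341	1	0.29	1	1	1.000	0.026	0.000
22	587	37	6.30	35	37	0.997	0.602	0.003
X	1118	8	0.72	7	8	1.000	0.062	0.000
Y	106	0	0.00	0	0	0.999	0.000	0.001
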