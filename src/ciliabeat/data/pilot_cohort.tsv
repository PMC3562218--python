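patient_id	group	pct_abnormal_total	pct_virtually_immotile	pct_stiff	pct_circular	dyskinesia_score	weighted_dist_um_per_s	weighted_area_um2_per_s	no_n_nl_min	tem_pct_abnormal	defect_label	cilia_orientation
1	PCD	85	55	30	0	2.40	1.2	3.3	15	100	IDA+NL	Poor
2	PCD	80	70	10	0	2.35	0.5	1.3	0	100	ODA	N
3	PCD	95	90	5	0	2.83	0.0	0.0	5.9	100	ODA	N
4	PCD	50	35	15	0	1.45	6.2	17.5	5.7	92	ODA	N
5	PCD	55	5	50	0	1.40	5.8	16.0	34	100	IDA+NL	N
6	PCD	75	30	45	0	2.03	5.2	12.9	4.2	100	ODA	N
7	PCD	10	5	5	0	0.25	27.1	87.9	59.8	100	ODA	N
8	PCD	100	90	10	0	2.95	0.6	1.8	11.1	100	ODA	N
9	PCD	100	100	0	0	3.00	0.0	0.0	6	100	ODA	N
10	PCD	100	100	0	0	3.00	0.0	0.0	13	100	ODA	N
11	non_PCD	0	0	0	0	0.00	53.3	184.6	809	7	No	N
12	non_PCD	10	0	10	0	0.25	82.8	267.8	260	1.5	No	N
13	non_PCD	5	0	5	0	0.15	53.7	148.2	219	2	No	N
14	non_PCD	5	0	5	0	0.15	77.0	256.6	194	9	No	N
15	non_PCD	0	0	0	0	0.00	76.1	236.2	661	6	No	N
16	non_PCD	10	0	10	0	0.25	80.9	248.8	183	2	No	N
17	non_PCD	20	0	20	0	0.50	75.6	251.5	100	7	No	N
18	non_PCD	20	0	20	0	0.50	34.1	95.8	639	3	No	N
19	non_PCD	25	0	25	0	0.63	67.7	218.7	282	2	No	N
20	non_PCD	25	20	5	0	0.73	68.1	199.8	784	3	No	N
21	non_PCD	20	0	20	0	0.50	39.9	116.8	264	15	CC	N
22	non_PCD	5	0	5	0	0.13	50.3	163.4	132	4	No	N
23	non_PCD	25	0	25	0	0.63	43.2	119.8	250	0	No	N
24	non_PCD	0	0	0	0	0.00	46.0	181.2	263	3	No	N
25	non_PCD	5	0	5	0	0.13	59.6	160.8	324	0	No	N
26	inconclusive	0	0	0	0	0.00	73.3	214.8	83	2	No	N
27	inconclusive	90	80	10	0	2.65	0.0	0.0	17	6.5	Heterogeneous	N
28	inconclusive	60	45	15	0	1.75	9.1	27.3	15	14	Heterogeneous	Poor
29	inconclusive	20	0	20	0	0.50	30.3	85.6	93	21	ODA	N
30	inconclusive	90	90	0	0	2.70	0.0	0.0	5	30	Heterogeneous	N
31	inconclusive	70	0	70	0	2.10	29.3	97.9	1	0	No	N
32	inconclusive	55	5	45	5	1.40	28.6	90.1	1	10	Heterogeneous	Poor
33	inconclusive	0	0	0	0	0.00	76.0	242.8	262	55	ODA+IDA	Poor
34	inconclusive	60	15	40	5	1.55	5.7	17.8	6.4	22	CC	N
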