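gene	gene_id	source	type	chromosome	aa	pi	mass	instability	aliphatic	gravy
HvLTP1.1	HORVU2Hr1G107470.2	barley	1	2	118	8.89	11560.52	23.32	85.42	0.613
HvLTP1.2	HORVU2Hr1G107480.1	barley	1	2	120	9.03	11856.79	31.67	84.75	0.55
HtLTP1.2	KAE8807755.1	qingke	1	2	120	9.03	11856.79	31.67	84.75	0.55
HvLTP1.3	HORVU2Hr1G107460.1	barley	1	2	125	9.82	12233.34	38.53	98.8	0.51
HtLTP1.3	KAE8775919.1	qingke	1	2	125	9.82	12233.34	38.53	98.8	0.51
HvLTP1.4	HORVU3Hr1G009560.1	barley	1	3	115	9.46	11221.08	25.46	89.39	0.487
HvLTP1.5	HORVU3Hr1G009510.1	barley	1	3	126	4.35	12730.43	61.65	82.22	0.213
HtLTP1.5	KAE8776966.1	qingke	1	3	126	4.35	12730.43	61.65	82.22	0.213
HvLTP1.6	HORVU3Hr1G009370.5	barley	1	3	115	9.32	11099.06	33.71	95.39	0.608
HtLTP1.6	KAE8788659.1	qingke	1	3	115	9.32	11099.06	33.71	95.39	0.608
HvLTP1.7	HORVU3Hr1G009490.4	barley	1	3	115	9.32	11175.17	34.44	92.78	0.59
HtLTP1.7	KAE8788658.1	qingke	1	3	115	9.32	11175.17	34.44	92.78	0.59
HvLTP1.8	HORVU3Hr1G009520.2	barley	1	3	115	9.88	11410.5	40	93.65	0.461
HtLTP1.8	KAE8788661.1	qingke	1	3	115	9.88	11410.5	40	93.65	0.461
HvLTP1.9	HORVU3Hr1G009360.8	barley	1	3	168	8.97	16215.03	34.24	106.07	0.749
HvLTP1.10	HORVU3Hr1G029430.1	barley	1	3	155	8.65	16185	28.35	89.61	0.61
HtLTP1.10	KAE8792517.1	qingke	1	3	155	8.65	16185	28.35	89.61	0.61
HvLTP1.11	HORVU4Hr1G022780.2	barley	1	4	111	8.7	10982.81	49.05	85.41	0.34
HtLTP1.11	KAE8800812.1	qingke	1	4	111	8.7	10982.81	49.05	85.41	0.34
HvLTP1.12	HORVU4Hr1G022770.1	barley	1	4	120	9.41	11746.77	42.01	93.75	0.631
HtLTP1.12	KAE8800813.1	qingke	1	4	120	9.41	11746.77	42.01	93.75	0.631
HvLTP1.13	HORVU5Hr1G046550.1	barley	1	5	117	8.7	12297.24	35.23	95.04	0.087
HtLTP1.13	KAE8791291.1	qingke	1	5	117	8.7	12297.24	35.23	95.04	0.087
HvLTP1.14	HORVU5Hr1G046520.1	barley	1	5	149	9.58	15377.09	45.4	87.85	0.316
HtLTP1.14	KAE8791289.1	qingke	1	5	149	9.58	15377.09	45.4	87.85	0.316
HvLTP1.15	HORVU7Hr1G080360.2	barley	1	7	120	3.74	12209.7	63.06	86.5	0.307
HtLTP1.15	KAE8796122.1	qingke	1	7	120	3.74	12209.7	63.06	86.5	0.307
HvLTP1.16	HORVU5Hr1G111050.1	barley	1	5	128	8.51	12881.01	49.5	88.67	0.403
HtLTP1.16	KAE8788807.1	qingke	1	5	128	8.51	12881.01	49.5	88.67	0.403
HvLTP2.1	HORVU1Hr1G083160.1	barley	2	1	91	9.27	9206.81	27.9	74.29	0.448
HtLTP2.1	KAE8821628.1	qingke	2	1	91	9.27	9206.81	27.9	74.29	0.448
HvLTP2.2	HORVU1Hr1G083170.1	barley	2	1	94	8.93	9370.08	41.66	92.66	0.511
HtLTP2.2	KAE8802268.1	qingke	2	1	94	8.93	9370.08	41.66	92.66	0.511
HvLTP2.3	HORVU2Hr1G108660.1	barley	2	2	95	7.48	9602.32	47.09	94.74	0.549
HtLTP2.3	KAE8821633.1	qingke	2	2	95	7.48	9602.32	47.09	94.74	0.549
HvLTP2.4	HORVU4Hr1G089490.2	barley	2	4	91	8.72	9439.32	37.88	92.42	0.502
HtLTP2.4	KAE8784379.1	qingke	2	4	91	8.72	9439.32	37.88	92.42	0.502
HvLTP2.5	HORVU4Hr1G089500.1	barley	2	4	97	9.72	10393.17	66.3	79.69	0.026
HtLTP2.5	KAE8777687.1	qingke	2	4	97	9.72	10393.17	66.3	79.69	0.026
HvLTPd1	HORVU1Hr1G043430.1	barley	D	1	139	9	14388.36	56.85	73.02	0.168
HvLTPd2	HORVU2Hr1G102110.1	barley	D	2	105	8.15	10966.95	41.92	94	0.4
HtLTPd2	KAE8788006.1	qingke	D	2	105	8.15	10966.95	41.92	94	0.4
HvLTPd3	HORVU2Hr1G102170.1	barley	D	2	113	4.85	11439.15	45.85	90.71	0.36
HtLTPd3	KAE8781084.1	qingke	D	2	113	4.85	11439.15	45.85	90.71	0.36
HvLTPd4	HORVU2Hr1G073730.1	barley	D	2	125	8.67	13033.35	55.43	100	0.131
HtLTPd4	KAE8786049.1	qingke	D	2	125	8.67	13033.35	55.43	100	0.131
HvLTPd5	HORVU2Hr1G102050.1	barley	D	2	105	8.47	10985.01	43.12	92.19	0.345
HtLTPd5	KAE8787999.1	qingke	D	2	105	8.47	10985.01	43.12	92.19	0.345
HvLTPd6	HORVU2Hr1G102100.1	barley	D	2	105	8.47	10994.02	41.29	92.19	0.348
HtLTPd6	KAE8788000.1	qingke	D	2	105	8.47	10994.02	41.29	92.19	0.348
HvLTPd7	HORVU2Hr1G104430.1	barley	D	2	132	7.53	14042.31	55.15	79.92	0.108
HtLTPd7	KAE8799817.1	qingke	D	2	132	7.53	14042.31	55.15	79.92	0.108
HvLTPd8	HORVU4Hr1G082600.1	barley	D	4	98	4.85	10347.06	55.61	81.84	0.105
HtLTPd8	KAE8799709.1	qingke	D	4	98	4.85	10347.06	55.61	81.84	0.105
HvLTPd9	HORVU7Hr1G102030.1	barley	D	7	114	8.14	11569.65	54.73	84.04	0.325
HtLTPd9	KAE8770127.1	qingke	D	7	114	8.14	11569.65	54.73	84.04	0.325
HvLTPd10	HORVU5Hr1G109100.1	barley	D	5	183	8.11	18559.7	29.33	105.19	0.509
HtLTPd10	KAE8808658.1	qingke	D	5	183	8.11	18559.7	29.33	105.19	0.509
HvLTPd11	HORVU7Hr1G026570.1	barley	D	7	103	9.22	10461.46	37.37	94.08	0.481
HtLTPd11	KAE8795354.1	qingke	D	7	103	9.22	10461.46	37.37	94.08	0.481
HvLTPg1	HORVU1Hr1G009490.1	barley	G	1	177	7.48	16847.26	44.5	86.21	0.482
HtLTPg1	KAE8777605.1	qingke	G	1	177	7.48	16847.26	44.5	86.21	0.482
HvLTPg2	HORVU2Hr1G098500.2	barley	G	2	189	6.06	19086.3	65.61	90.9	0.439
HtLTPg2	KAE8795728.1	qingke	G	2	189	6.06	19086.3	65.61	90.9	0.439
HvLTPg3	HORVU4Hr1G071790.1	barley	G	4	194	5.52	18793.44	67.86	80.26	0.389
HtLTPg3	KAE8805373.1	qingke	G	4	194	5.52	18793.44	67.86	80.26	0.389
HvLTPg4	HORVU5Hr1G109040.1	barley	G	5	197	8.66	19981.15	44.98	86.4	0.335
HtLTPg4	KAE8808654.1	qingke	G	5	197	8.66	19981.15	44.98	86.4	0.335
HvLTPg5	HORVU5Hr1G076000.1	barley	G	5	190	4.41	19076.74	68.97	76.26	0.295
HtLTPg5	KAE8769277.1	qingke	G	5	190	4.41	19076.74	68.97	76.26	0.295
HvLTPg6	MLOC_57612.1	barley	G	5	176	8.47	17033.39	52.61	81.7	0.372
HvLTPg7	HORVU0Hr1G016430.1	barley	G	Un	174	7.5	17574.28	46.75	91.61	0.277
HtLTPg7	KAE8793545.1	qingke	G	Un	174	7.5	17574.28	46.75	91.61	0.277
HvLTPg8	HORVU6Hr1G082080.1	barley	G	6	200	8.76	19385.55	85.08	93.3	0.485
HtLTPg8	KAE8808175.1	qingke	G	6	200	8.76	19385.55	85.08	93.3	0.485
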