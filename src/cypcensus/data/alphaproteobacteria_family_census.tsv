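family	count	percentage	subfamily	subfamily_count
CYP1010	1	0.11%	A	1
CYP1017	1	0.11%	A	1
CYP101	10	1.14%	B	1
			C	3
			D	2
			E	2
			Q	1
			R	1
CYP102	12	1.37%	A	10
			K	1
			AC	1
CYP1036	2	0.23%	B	1
			C	1
CYP103	4	0.46%	A	4
CYP104	13	1.49%	A	13
CYP105	4	0.46%	BF	3
			CX	1
CYP1061	2	0.23%	B	2
CYP1068	4	0.46%	A	4
CYP1075	1	0.11%	A	1
CYP1076	1	0.11%	A	1
CYP1077	1	0.11%	A	1
CYP1078	8	0.92%	A	7
			C	1
CYP107	10	1.14%	AN	8
			_	1
			JE	1
CYP1081	2	0.23%	B	2
CYP1082	1	0.11%	A	1
CYP1083	5	0.57%	A	3
			C	2
CYP1086	1	0.11%	B	1
CYP1088	2	0.23%	B	2
CYP1089	1	0.11%	A	1
CYP108	37	4.23%	A	2
			D	6
			G	18
			L	1
			P	2
			U	1
			V	1
			W	1
			X	5
CYP1090	2	0.23%	C	2
CYP1091	3	0.34%	A	3
CYP1094	4	0.46%	A	3
			B	1
CYP1098	6	0.69%	A	6
CYP1101	29	3.32%	A	29
CYP1104	10	1.14%	A	4
			C	3
			E	3
CYP1107	16	1.83%	A	12
			B	3
			C	1
CYP1111	7	0.80%	A	5
			B	1
			C	1
CYP1116	3	0.34%	B	3
CYP1118	1	0.11%	B	1
CYP111	2	0.23%	A	1
			B	1
CYP112	23	2.63%	A	23
CYP1135	1	0.11%	A	1
CYP1137	1	0.11%	A	1
CYP1138	2	0.23%	B	2
CYP1141	1	0.11%	A	1
CYP1145	1	0.11%	A	1
CYP114	22	2.52%	A	22
CYP1155	1	0.11%	B	1
CYP115	1	0.11%	A	1
CYP116	1	0.11%	B	1
CYP1170	7	0.80%	A	7
CYP1171	1	0.11%	A	1
CYP1173	1	0.11%	A	1
CYP1174	2	0.23%	A	2
CYP1175	1	0.11%	A	1
CYP117	22	2.52%	A	22
CYP1181	1	0.11%	A	1
CYP1182	1	0.11%	A	1
CYP1186	2	0.23%	A	2
CYP1187	1	0.11%	A	1
CYP1204	2	0.23%	A	2
CYP1206	1	0.11%	B	1
CYP1221	2	0.23%	B	2
CYP1229	4	0.46%	A	1
			B	2
			C	1
CYP1246	2	0.23%	A	2
CYP1250	1	0.11%	A	1
CYP1258	1	0.11%	A	1
CYP125	1	0.11%	P	1
CYP1275	1	0.11%	B	1
CYP127	19	2.17%	A	18
			C	1
CYP1281	1	0.11%	A	1
CYP1291	5	0.57%	B	3
			C	2
CYP1302	2	0.23%	A	2
CYP1311	2	0.23%	A	2
CYP1312	1	0.11%	A	1
CYP1326	2	0.23%	B	2
CYP1330	1	0.11%	A	1
CYP1337	1	0.11%	A	1
CYP133	1	0.11%	F	1
CYP1349	1	0.11%	A	1
CYP1350	1	0.11%	A	1
CYP1371	1	0.11%	B	1
CYP1376	2	0.23%	B	1
			C	1
CYP1384	1	0.11%	A	1
CYP1396	1	0.11%	A	1
CYP1405	1	0.11%	B	1
CYP1406	3	0.34%	B	2
			C	1
CYP1460	1	0.11%	C	1
CYP147	16	1.83%	D	16
CYP1515	2	0.23%	A	2
CYP151	2	0.23%	C	2
CYP152	13	1.49%	B	4
			C	3
			E	2
			P	1
			AA	1
			AB	2
CYP153	60	6.86%	A	44
			C	2
			D	14
CYP155	4	0.46%	J	3
			K	1
CYP1591	1	0.11%	A	1
CYP1597	1	0.11%	A	1
CYP1732	3	0.34%	A	3
CYP1733	2	0.23%	A	1
			B	1
CYP1734	1	0.11%	A	1
CYP1735	1	0.11%	A	1
CYP1736	1	0.11%	A	1
CYP1737	2	0.23%	A	2
CYP1738	1	0.11%	A	1
CYP1739	2	0.23%	A	2
CYP173	60	6.86%	A	45
			B	8
			C	3
			G	1
			H	1
			J	2
CYP1740	1	0.11%	A	1
CYP1741	1	0.11%	A	1
CYP1742	1	0.11%	A	1
CYP1743	1	0.11%	A	1
CYP1744	1	0.11%	A	1
CYP1745	1	0.11%	A	1
CYP1746	1	0.11%	A	1
CYP1747	1	0.11%	A	1
CYP1748	1	0.11%	A	1
CYP1749	2	0.23%	A	1
			B	1
CYP1750	1	0.11%	A	1
CYP1751	1	0.11%	A	1
CYP1752	4		A	4
CYP1753	1	0.11%	A	1
CYP1754	1	0.11%	A	1
CYP1755	1	0.11%	A	1
CYP180	1	0.11%	D	1
CYP186	7	0.80%	K	7
CYP191	1	0.11%	B	1
CYP192	3	0.34%	A	3
CYP193	17	1.95%	A	17
CYP194	10	1.14%	A	10
CYP195	21	2.40%	A	18
			D	1
			E	2
CYP196	37	4.23%	A	34
			B	2
			C	1
CYP197	2	0.23%	R	2
CYP199	16	1.83%	A	11
			B	1
			J	1
			K	1
			L	1
			M	1
CYP200	8	0.92%	A	5
			B	2
			C	1
CYP201	31	3.55%	A	25
			B	3
			C	3
CYP202	70	8.01%	A	46
			B	24
CYP203	13	1.49%	A	12
			B	1
CYP204	2	0.23%	A	2
CYP206	19	2.17%	A	9
			B	1
			C	3
			D	6
CYP219	2	0.23%	A	2
CYP223	3	0.34%	A	2
			E	1
CYP224	1	0.11%	A	1
CYP225	7	0.80%	A	7
CYP226	2	0.23%	C	1
			D	1
CYP278	2	0.23%	A	1
			C	1
CYP286	1	0.11%	C	1
CYP288	2	0.23%	B	2
CYP289	33	3.78%	A	33
CYP290	6	0.69%	A	5
			B	1
CYP2140	1	0.11%	A	1
CYP1236	1	0.11%	A	1
CYP2334	2	0.23%	A	2
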