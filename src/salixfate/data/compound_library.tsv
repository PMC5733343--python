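peak_id	name	rt_min	printed_mass_da	formula	printed_delta_ppm	identification_level	salix_described	known_gut_metabolite	curation_note
1	saccharose	1.33	342.1166	C12H22O11	4.14	tentative	0	0
2	malic acid	1.43	134.0203	C4H6O5	-1.35	tentative	0	0
3	citric acid	1.66	192.0263	C6H8O7	1.94	reference	0	0
4	succinic acid	1.96	118.0252	C4H6O4	-2.42	reference	0	0
5	isopropyl maleate	2.65	158.0565	C7H10O4	-2.00	tentative	0	0
6	protocatechuic acid	4.93	154.0252	C7H6O4	-2.32	reference	0	1
7	(epi)gallocatechin	5.17	306.0742	C15H14O7	5.12	tentative	1	0
8	catechol	5.62	110.0352	C6H6O2	-2.99	tentative	0	0
9	vanillic acid hexoside	6.08	330.0957	C14H18O9	5.26	tentative	1	0
10	salicin	6.72	286.1055	C13H18O7	3.78	reference	1	0
11	cysteine-saligenin-adduct	6.98	227.0611	C10H13O3NS	1.94	tentative	0	0
12	saligenin	7.06	124.0512	C7H8O2	-1.51	reference	1	0
13	5-(3',4',5'-trihydroxyphenyl)-gamma-valerolactone	7.68	224.0677	C11H12O5	1.26	tentative	0	1
14	gentisic acid	7.70	154.0252	C7H6O4	-2.25	reference	0	0
15	4-hydroxybenzoic acid	7.72	138.0301	C7H6O3	-3.51	reference	0	0
16	4-hydroxy-5-(dihydroxyphenyl)valeric acid	8.88	226.0834	C11H14O5	1.60	tentative	0	1
17	dihydrocaffeic acid	9.13	182.0570	C9H10O4	2.01	reference	0	1
18	(epi)catechin-(epi)catechin	9.23	578.1430	C30H26O12	2.82	tentative	1	0
19	catechin	9.62	290.0793	C15H14O6	4.59	reference	1	0
20	4-oxo-5-(dihydroxyphenyl)valeric acid	9.79	224.0677	C11H12O5	1.26	tentative	0	1
21	dihydroxybenzoic acid	9.87	154.0251	C7H6O4	-2.37	tentative	0	0
22	hydroxy(iso)caproic acid	10.52	132.0771	C6H12O3	-3.74	tentative	0	1
23	acetylsalicin	10.54	328.1161	C15H20O8	3.82	tentative	1	0
24	hydroxy(iso)caproic acid	10.88	132.0771	C6H12O3	-3.68	tentative	0	1
25	chlorogenic acid	10.92	354.0955	C16H18O9	4.48	reference	1	0
26	(epi)catechin-(epi)catechin-(epi)catechin	10.95	866.2067	C45H38O18	2.47	tentative	1	0
27	syringin	11.38	372.1421	C17H24O9	4.44	tentative	1	0
28	5-(dihydroxyphenyl)-gamma-valerolactone	12.34	208.0726	C11H12O4	0.07	tentative	0	1
29	benzyl-hexoside-pentoside	12.40	402.1539	C18H26O10	4.50	tentative	0	0
30	ampelopsin	12.42	320.0533	C15H12O8	4.16	tentative	1	0
31	dihydroquercetin sulfate	12.83	314.0156	C15H12O10S	1.56	tentative	0	0	printed mass inconsistent with printed formula (C15H12O10S computes to 384.0151 Da)
32	benzyl-hexoside-pentoside	12.89	402.1541	C18H26O10	4.95	tentative	0	0
33	acetylsalicin	14.39	328.1159	C15H20O8	3.42	tentative	1	0
34	3-(3-hydroxyphenyl)propionic acid	14.65	166.0616	C9H10O3	-1.88	reference	0	1
35	4-hydroxy-5-(hydroxyphenyl)valeric acid	16.61	210.0882	C11H14O4	0.55	tentative	0	1
36	dihydroquercetin	17.78	304.0585	C15H12O4	4.62	reference	1	0	printed formula inconsistent with printed mass (C15H12O4 computes to 256.0736 Da)
37	(+)-naringenin-5-glucoside	17.89	434.1215	C21H22O10	3.64	tentative	1	0
38	salicylic acid	17.99	138.0302	C7H6O3	-3.29	reference	1	0
39	rosarin	18.34	428.1683	C20H28O10	3.08	tentative	0	0
40	salicortin	18.49	424.1371	C20H24O10	1.79	tentative	1	0
41	(-)-naringenin-5-glucoside	18.84	434.1215	C21H22O10	3.09	tentative	1	0
42	5-(dihydroxyphenyl)valeric acid	19.65	210.0882	C11H14O4	0.31	tentative	0	1
43	cinnamyl-(6'-O-xylopyranosyl)-O-glucopyranoside	19.66	428.1690	C20H28O10	2.94	tentative	0	0
44	hyperoside	20.70	464.0957	C21H20O12	4.27	reference	1	0
45	cinnamyl-hexoside-deoxyhexoside	20.95	442.1840	C21H30O10	2.80	tentative	0	0
46	dihydrocinnamyl-hexoside-deoxyhexoside	21.52	444.2001	C21H32O10	3.42	tentative	0	0
47	naringenin-7-glucoside	21.90	434.1215	C21H22O10	1.58	reference	1	0
48	salireposide	22.34	406.1268	C20H22O9	3.28	tentative	1	0
49	phenylpropionic acid	24.15	150.0670	C9H10O2	-0.35	tentative	0	1
50	acetylsalicortin	24.79	466.1475	C22H26O11	1.86	tentative	1	0
51	grandidentatin/isograndidentatin	24.97	424.1730	C21H28O9	4.23	tentative	1	0
52	isosalipurposide	25.40	434.1211	C21H22O10	3.99	tentative	1	0
53	grandidentatin/isograndidentatin	25.46	424.1740	C21H28O9	4.02	tentative	1	0
54	hydroxyphenylvaleric acid	25.87	194.0930	C11H14O3	0.00	tentative	0	1	printed mass deviates from printed formula by -6.7 ppm (C11H14O3 computes to 194.0943 Da)
55	benzoylsalicin	27.51	390.1320	C20H24O9	3.07	tentative	1	0	printed mass inconsistent with printed formula (C20H24O9 computes to 408.1420 Da; printed mass matches C20H22O8)
56	naringenin	30.77	272.0683	C15H12O5	4.58	reference	1	0
57	HCH-acetylsalicortin	32.46	604.1893	C29H32O14	2.45	tentative	1	0	printed mass deviates from printed formula by +16.7 ppm (C29H32O14 computes to 604.1792 Da)
58	tremulacin	35.54	528.1630	C27H28O11	1.73	tentative	1	0
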