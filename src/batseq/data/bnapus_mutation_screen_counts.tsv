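lane	pool	gene	position	ref_base	A	C	G	T	ratio	wt_aa	mut_aa
6	B00146	BnaC.FAD2.a	37	G	183	0	1640	0	0.111585	Glu	Lys
5	B00282	BnaC.FAD2.a	45	C	0	3555	0	246	0.069198	Leu	Leu
4	B00009	BnaC.FAD2.a	46	C	7	5431	2	77	0.014178	Glu	STOP
4	B00282	BnaC.FAD2.a	57	C	0	2032	1	164	0.080709	Ile	Ile
4	B00136	BnaC.FAD2.a	59	C	0	2176	0	59	0.027114	Ser	Phe
4	B00077	BnaC.FAD2.a	68	G	137	0	1524	1	0.089895	Gly	Asp
6	B00087	BnaC.FAD2.a	227	C	0	143	0	14	0.097902	Ser	Leu
6	B00040	BnaC.FAD2.a	249	G	11	0	931	0	0.011815	Arg	Arg
6	B00207	BnaA.FAD2.a	43	C	3	14174	0	147	0.010371	N/A	N/A
4	B00108	BnaA.FAD2.a	45	C	2	12350	0	319	0.02583	N/A	N/A
5	B00136	BnaA.FAD2.a	45	C	0	4566	0	298	0.065265	N/A	N/A
6	B00041	BnaA.FAD2.a	45	C	1	5883	0	68	0.011559	N/A	N/A
4	B00208	BnaA.FAD2.a	48	G	309	0	5574	0	0.055436	N/A	N/A
5	B00119	BnaA.FAD2.a	48	G	940	8	15594	0	0.06028	N/A	N/A
6	B00114	BnaA.FAD2.a	63	C	1	8285	0	88	0.010622	N/A	N/A
6	B00147	BnaA.FAD2.a	63	C	2	9325	0	861	0.092332	N/A	N/A
4	B00108	BnaA.FAD2.a	64	G	1065	3	10533	0	0.101111	N/A	N/A
6	B00134	BnaA.FAD2.a	69	C	4	8271	0	237	0.028654	N/A	N/A
4	B00058	BnaA.FAD2.a	225	C	2	5339	0	316	0.059187	N/A	N/A
6	B00075	BnaA.FAD2.a	238	G	181	0	1314	1	0.137747	N/A	N/A
4	B00044	BnaA.FAD2.a	248	G	40	0	2640	0	0.015152	N/A	N/A
5	B00282	BnaA.FAD2.a	248	G	29	0	846	2	0.034279	N/A	N/A
4	B00073	BnaA.FAD2.b	37	G	53	0	1062	0	0.049906	N/A	N/A
5	B00285	BnaA.FAD2.b	39	G	27	0	1471	0	0.018355	N/A	N/A
5	B00213	BnaA.FAD2.b	39	G	6170	36	59711	4	0.103331	N/A	N/A
6	B00128	BnaA.FAD2.b	40	C	9	30818	0	1156	0.037511	N/A	N/A
4	B00027	BnaA.FAD2.b	43	C	26	72577	1	6652	0.091654	N/A	N/A
4	B00180	BnaA.FAD2.b	45	C	9	26921	0	824	0.030608	N/A	N/A
4	B00260	BnaA.FAD2.b	45	C	11	31793	2	1069	0.033624	N/A	N/A
5	B00135	BnaA.FAD2.b	45	C	1	4675	0	114	0.024385	N/A	N/A
5	B00211	BnaA.FAD2.b	45	C	9	67246	3	5206	0.077417	N/A	N/A
5	B00243	BnaA.FAD2.b	45	C	5	87630	1	4416	0.050394	N/A	N/A
6	B00299	BnaA.FAD2.b	48	G	335	1	13245	1	0.025293	N/A	N/A
4	B00090	BnaA.FAD2.b	59	C	34	127784	1	2404	0.018813	N/A	N/A
5	B00087	BnaA.FAD2.b	59	C	3	8544	0	744	0.087079	N/A	N/A
5	B00223	BnaA.FAD2.b	63	C	28	64330	0	12219	0.189942	N/A	N/A
6	B00250	BnaA.FAD2.b	63	C	2	1965	0	413	0.210178	N/A	N/A
5	B00111	BnaA.FAD2.b	68	G	249	1	3179	1	0.078327	N/A	N/A
6	B00195	BnaA.FAD2.b	219	C	0	2666	0	28	0.010503	N/A	N/A
6	B00118	BnaA.FAD2.b	237	G	20	0	2055	0	0.009732	N/A	N/A
5	B00105	BnaA.FAD2.b	265	G	97	0	352	0	0.275568	N/A	N/A
6	B00118	BnaC.GL2.b	46	C	14	46512	3	1058	0.022747	intron	
5	B00249	BnaC.GL2.b	65	G	330	2	20270	9	0.01628	Ile	Ile
4	B00104	BnaC.GL2.b	68	C	1	7275	1	67	0.00921	Arg	Arg
4	B00064	BnaC.GL2.b	109	C	6	32767	4	121	0.003693	Val	Met
4	B00307	BnaC.GL2.b	110	C	7	38693	2	784	0.020262	Ala	Ala
4	B00076	BnaC.GL2.b	113	C	5	32262	0	70	0.00217	Lys	Lys
6	B00091	BnaC.GL2.b	122	C	11	78003	2	1427	0.018294	Leu	Leu
6	B00228	BnaC.GL2.b	130	C	5	16523	2	191	0.01156	Ala	Thr
5	B00147	BnaC.GL2.b	143	C	1	14670	4	220	0.014997	Trp	STOP
6	B00115	BnaC.GL2.b	143	C	17	76370	43	347	0.004544	Trp	STOP
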