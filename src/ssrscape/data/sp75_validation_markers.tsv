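sn	name	motif	forward	reverse	product_size	tm	na	he	pic
1	chr01_3_3996646	(ACA)11	CTACAATGGAACCACCCTAGC	TAGTTCAGGCTATCAGCTCCAA	114	59	4	0.42	0.31
2	chr05_3_22933154	(ACA)23	TCCTCTCTCCATTTGCAACC	CCCCAACTCTTCTTGTCAGC	173	60	5	0.41	0.30
3	chr03_4_53804930	(TTGT)7	CGAGCTGTGAAGGTATTTCTTGG	AATTTGTGTTTTGCGCTTC	213	59	2	0.49	0.25
4	chr04_5_76909578	(CAGGC)4	TTCCGGTGTTCTGAAACTACAT	TCCTTTCATTGTTGCTTGG	272	59	NA	NA	NA
5	chr06_6_22506385	(AGGCAA)6	ACAGCACAAGCCACAAAATG	GTGGTACTGGCGGTAGTGCT	307	60	3	0.33	0.28
6	chr04_3_112691959	(ACA)13	AACAAATTCGCACCACATCA	AAGATGTTGGCCGACGATAG	399	60	3	0.38	0.27
7	chr03_3_99679126	(TTG)10	GAAAACTTCGCGTTACAATGAGC	ATTTCCGAGTGATCTTGAGC	122	59	3	0.45	0.32
8	chr06_2_37161425	(GA)8	GAGCTTAACAACCGAGCTTGA	GGAATTTTGGGTTGACGTGT	185	60	2	0.48	0.24
9	chr06_3_40415854	(TCA)10	AGCCTATACACACTCCTCTCGG	CTTCTAGGTCCGGTTTCCATC	221	60	3	0.26	0.22
10	chr02_3_30545229	(AGA)10	ATCCCAGCAGTAAACCAACC	AACAGCTTCCTTGCTTGCAT	292	59	3	0.39	0.27
11	chr04_3_54423372	(ACC)5	AGAAACAAAGGCGAGGTACG	CAGATATCGGAATCGCAAGA	340	59	2	0.44	0.18
12	chr02_3_41041559	(TCA)13	GGCTCACCATTTTGGTCATT	ATTGGAAGCATGCAAGGAGT	389	60	3	0.47	0.27
13	chr02_5_18463938	(AGGGA)4	TTAGCAAACACCAAAAATTGGA	GAACACCAAATGTTGCATGG	126	60	2	0.24	0.12
14	chr02_6_52639756	(AGAGAA)4	AAACCACATACAGGGCCTCA	TACACCACACAGCGTCCACT	187	60	3	0.47	0.30
15	chr05_3_55104642	(GAG)6	TTAAGTCAGAAACCTTCCCCTG	TCTTCCATCATTTACGCCAAG	225	60	2	0.46	0.21
16	chr03_6_29450333	(CAAATT)4	ACCCAATAAAACAGCGATGC	CCAAGCTGTCACAAAACACG	276	60	2	0.45	0.24
17	chr02_3_60571150	(AAC)11	AGCTAAACTCCGTGGCACAT	AGAAGGGAGTGGAGGGAGAG	313	60	3	0.44	0.23
18	chr05_3_32205256	(ATC)9	ATGTTGGCCTGATCCATTGT	CGTGAGCAACTGATGGGAAT	388	61	2	0.34	0.22
19	chr03_3_9824683	(ATG)6	CCATGAGGAACAACACTAGCAAC	CATCTCACAGACAATCTCACAG	108	60	2	0.36	0.13
20	chr01_3_47220474	(TTG)7	GGTTCATGTAGCCGACCCTA	AGGTGGAGAACAAGGAAAGAA	189	59	3	0.36	0.27
21	chr06_3_17100717	(TCT)7	TGATACCAATACCTGCACACAAG	GTGTTAAAGGACCCGTTTTC	241	59	2	0.41	0.18
22	chr04_3_42840013	(GCA)9	AAGCTTCCATCTTTGGCTCA	AAAGTCGCTTGCAGTCGTTT	293	60	NA	NA	NA
23	chr03_3_75066435	(AGA)17	CTTGCCTCCAATTTGCATTT	TGTGAGAGTCGGAGAATCCTT	339	59	2	0.41	0.30
24	chr03_3_20380054	(TTC)11	CCTACCACTTTCATCTCATCCAG	TGTAAACAGAACCACCCATGA	391	59	3	0.42	0.32
25	chr05_3_1063291	(TCA)17	ATGAAGGCAAGATTTCGGTACTC	TCAACCACGACATGAACCTTA	135	60	4	0.36	0.23
26	chr04_3_31208653	(CAG)10	CCTCATCATTGTCCTCATCAAGA	CTGCCGAGAACTGCATAAACT	173	60	4	0.46	0.32
27	chr03_3_295631	(GAA)9	CAAAATGGAAACCCCAACAACA	CAGAACAACCCAAACTCAAA	216	60	3	0.36	0.27
28	chr05_4_64332729	(TGTA)9	GGTTTCATCAATCTTCCTGCATC	CAGGTTCAAAATGCTCCATA	257	60	5	0.41	0.35
29	chr06_3_44057430	(CCA)6	CCACAAACTGCCCTAAATGG	AACCATGGCTCATGTTGATG	304	60	2	0.39	0.14
30	chr01_4_18090562	(TATC)6	AAAGGGCAGAGAGAAGAAAGATG	TCATGCTGAAGTGACCGAAC	350	60	2	0.35	0.09
31	chr01_6_26485152	(CAACAG)4	AACCAAAAGGCAACAAAAATGTT	TTGAACAACCCCGATAGC	135	59	4	0.42	0.29
32	chr05_6_42561823	(CTGCTA)5	TGGTGGCTGGTCATAAGTATTGC	TAACAGAAGCAGCAGCAGAAG	175	60	3	0.40	0.26
33	chr01_6_42933346	(GGTGTG)5	GTTGAAGACGCTGTAGTTCGGCC	CCTTCGCAATACTCCTTAAT	238	60	4	0.40	0.31
34	chr01_4_37404206	(ATGT)8	CCAATGCAAGGGTAACACAATTC	TCAGCCATCTGTTGATCTGTA	290	60	3	0.35	0.24
35	chr04_3_5365603	(TTC)9	ATCTCGTGCCAACCATAACC	TTGATCAGAGGACAAAGAAAGC	245	59	4	0.40	0.35
36	chr06_3_4451765	(AGG)7	ACCCCATTTCTTCCCTCTTT	TTTAAGATCAACCAACGCCTTCT	380	60	3	0.34	0.29
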