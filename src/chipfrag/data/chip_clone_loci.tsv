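clone	length_bp	at_percent	localization	gene	location_to_gene	distance_to_gene
41	105	61	1p35	PTPRU	upstream	180 kb
28	403	68	1q25	SEC16B	downstream	70 kb
3	440	61	1q25.1	TNR	intron 1	-
23	253	63	1q31	KCNT2	downstream	1000 kb
14	652	69	1q31.1	FDPSL1	downstream	300 kb
27	1017	57	1q42	CDC42BPA	intron 21	-
8	715	68	2p13.3	GKN3P	intron 1	-
2	373	65	2p24.1	WDR35	intron 34	-
29	316	47	2q31	HOXD10	exon 2	-
48	1612	54	3p21	LARS2	intron 13	-
45	1592	59	3p22	STAC	downstream	170 kb
44	234	70	3q26.1	SI	downstream	25 kb
49	157	52	3q26.1	KPNA4	intron 1	-
40	171	62	4p15.1	ARAP2	downstream	2000 kb
16	395	63	4q31.1	CLGN	upstream	500 bp
12	981	69	4q32.3	SPOCK3	upstream	300 kb
10	350	73	4q34.3	RPL19P8	downstream	15 kb
39	561	60	5p14	PRDM9	downstream	117 kb
32	1080	61	6p22	DCDC2	intron 2	-
22	574	67	6q16	TSG1	upstream	113 kb
20	574	67	6q22	NKAIN2	intron 1	-
6	639	62	6q22.31	MAN1A1	downstream	830 kb
35	233	68	6q23	VNN3	upstream	900 bp
34	105	74	7q22	RELN	intron 33	-
17	323	58	7q36.1	ACTR3C	upstream	9 kb
4	492	72	8q21.12	PKIA	upstream	220 kb
7	219	72	8q23.2	PKHD1L1	intron 16	-
13	161	72	9q21.12	ALDH1A1	upstream	90 kb
36	276	52	9q22	COL15A1	intron 1	-
30	765	50	9q34	ENG	intron 8	-
46	180	69	10p11.2	CCDC7	downstream	32 kb
43	300	60	10p13	FAM107B	intron 2	-
15	305	71	10q21.3	JMJD1C	intron 22	-
5	1848	67	13q32.3	FGF-14	intron 1	-
11	363	71	14q21.3	RPL10L	downstream	350 kb
24	142	64	14q32	PPP4R4	intron 2	-
42	695	52	17q21	PLEKHM1	upstream	3 kb
33	1220	61	17q22	MBTD1	intron 6	-
19	508	51	17q23.3	RGS9	intron 19	-
18	495	64	18p11.22	PPP4R1	intron 23	-
31	412	60	18q21	STARD6	upstream	149 kb
26	287	64	19q12	ZNF99	downstream	25 kb
47	359	66	19q13.1	FCGBP	intron 3	-
9	511	66	20q13.11	PTPRT	intron 1	-
1	500	56	20q13.13	NFATC2	downstream	6.5 kb
25	235	46	21q22	RUNX1	intron 5	-
21	201	54	unplaced	-	-	-
37	633	62	unplaced	-	-	-
38	388	79	unplaced	-	-	-
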