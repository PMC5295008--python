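genome_pos	strand	gene_label	codon	aa_conversion	flags	Leaf-1	Leaf-2	Leaf-3	Leaf-4	Leaf-5	Pistil-1	Root-1	Root-2	Root-3	Root-4	Seed-1	Seed-2	Seed-3	Sheath-1	Sheath-2	Sheath-3	Sheath-4	Spike-1	Spike-2	Spike-3	Stamen-1	Stem-1	Stem-2	Stem-3
3090	sense	~psbK									22																		
3551	sense	~psbK									7																		
8259	sense	psbI~psbD				35	36	37	36	37				47	44				33	29	32	33			25	22			
8481	sense	psbI~psbD									9																		
11311	sense	psbC~psbZ				21		19	20		18										10				10		9		
20093	sense	rpoB-467	tCg	S>L	a					38	28								66	75	78	90				72			32
20171	sense	rpoB-545	tCa	S>L	a						48								70	86	88	78				71			
20186	sense	rpoB-560	tCg	S>L	a						57								73	86	80	85				69			
29181	sense	rpoC2-4031	tCg	S>L	a	94	+	+	91	98	+			+	82	71	60	73	97	99	93	97	92		+	92	99		98
32404	sense	atpH~atpF							18	18						15													
34440	sense	atpA-234	ggC	G>G							11																		
35354	sense	atpA-1148	tCa	S>L	a	99	98	99	99	99		83	94	98	91	94	91	87	96	90	94	96	95		94	71	93	95	94
42415	sense	atpA~trnS-GGA																		14									
57960	sense	ycf4~cemA				52	50	67	48	55	12								37	42	27	31				23			26
62758	sense	petL-56	cCa	P>L	d	83	75	62	77	60									58		36	30					83		
65352	sense	rps18-448	Cga	R>Stop							9																		
68447	sense	psbB-414	atC	L>L																					17				
71835	sense	petB-662	cCa	P>L	a	96	98	97	98	90						43		27				34			66	58	26		13
127814	sense	ndhB-149	tCa	S>L	a	94																96							
128251	sense	ndhB-586	Cat	H>Y	a	95	88	91	93	93																			
128276	sense	ndhB-611	tCa	S>L	a	95		93	95	94																			
128369	sense	ndhB-704	tCc	S>F	a				92																				
129858	sense	ndhB-1481	cCa	P>L	a	96	99	99		97																			
1956	antisense	matK-1261	Cat	H>Y	a	66	45	41	69	52	13			36					69	55	38	69	55		50	36	61		71
5100	antisense	rps16-intron				19	17	22	23	22	89	54	51	50		65			36	33	32	37	83		83	60	66	70	60
5179	antisense	rps16-intron										15	15	23															
36673	antisense	rps14~psaB				45	45	45	44	45									20		20	14			19	23			8
42982	antisense	ycf3-191	aCg	T>M	a	79	83	82	81	80	63	44	55	45	39			49	70	69	67	63	64		74	64	72		76
43880	antisense	ycf3-44	tCc	S>F	a	92	92	96	97	92	40	71	68	70	26	46			70	70	69	82	42		50	43	69	77	74
44727	antisense	ycf3~rps4				78	68	71	75	65	38					41			35	29	35	19					20	21	
44868	antisense	ycf3~rps4									11																		
45244	antisense	rps4-305	tCa	S>L												20													
49393	antisense	ndhK-125	cCa	P>L	d	99	98	99	99	99	+			70	+	71			96	97	94	94	+		93	89	95		89
49858	antisense	ndhC-13	Cac	H>Y		98	98	98	99	99	75	86	83	63	63	86			86	92	85	91			56	80	83		63
61027	antisense	psbL-111	ttC	F>F		77	83	83	81	49	76								47	45	33	29				56			
65383	antisense	trnP-GGG~rpl20						24																					
65632	antisense	rpl20-308	tCa	S>L	a			11		24									60	38	63	75				56			
67968	antisense	clpP~psbN				31																							
73402	antisense	psbN~rpoA				45	50	51	51	45				35					19	12	13	21	20			15	14		22
73980	antisense	rpoA-527	tCc	S>F	d	30	34	30	28	28		23	18	31	35	79	64	72	81	84	81	90	84	75	85	41	87	82	86
74553	antisense	rpoA~rps11				41	44	44	45	41	21		19	11	29	15	12	22	21	20	22	18	18		18	17	23	20	20
76074	antisense	rps8-182	tCa	S>L	a	89	90	89	90	90	96	83	86	83	84	96	96	95	97	97	97	97	93	95	93	96	95	95	95
77285	antisense	rpl16-36	ccC	P>P							18																		
78313	antisense	rpl16~rps3									92																		
79174	antisense	rps3-30	ttC	F>F	d	62	57	62	66	59	77	58	66	71	69	78	82	63	66	68	69	71	68	63	63	62	56	57	48
81816	antisense	rpl2~rpl23									82								87	88	88								
86095	antisense	ndhB-836	tCa	S>L	a					99																			
87176	antisense	ndhB-467	cCa	P>L	a	99	95	96	97	98										96		89							
87494	antisense	ndhB-149	tCa	S>L	a		95																						
96705	antisense	rps7~trnN-GUU				6			12																				
101658	antisense	ndhF-1891	Cag	Q>Stop							9																		
103487	antisense	ndhF-62	tCa	S>L	a	45	43	44	49	51						28			39	39	43	18			21	17	44		37
106742	antisense	ndhD-1398	atC	L>L	d	36	28	37	34	37																			23
107262	antisense	ndhD-878	tCa	S>L	a,d	99	98	99	99	98				+		89	95		89	81	89	77	84		77	94	89	+	83
109393	antisense	ndhE~ndhG								32																			
109684	antisense	ndhG-347	cCa	P>L	d	98	97	97	98	96									65	59	64	72				40	78		65
110034	antisense	ndhG~ndhI				38	27	22	28	19																			
110946	antisense	ndhA-1070	tCt	S>F	a	75			64	92																			
111453	antisense	ndhA-563	tCa	S>L	a	13																							
112572	antisense	ndhA-473	tCa	S>L	a			+											45	33									
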