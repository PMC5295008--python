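gene	nt_pos	aa_pos	codon_conversion	aa_conversion	validation
ndhA	473	158	tCa>tTa	S>L	a
ndhA	563	188	tCa>tTa	S>L	a
ndhA	1070	357	tCt>tTt	S>F	
atpA	1148	383	tCa>tTa	S>L	a
atpB	1487	496	tCg>tTg	S>L	
matK	1261	421	Cat>Tat	H>Y	a
ndhB	149	50	tCa>tTa	S>L	a
ndhB	467	156	cCa>cTa	P>L	a
ndhB	586	196	Cat>Tat	H>Y	a
ndhB	611	204	tCa>tTa	S>L	a
ndhB	704	235	tCc>tTc	S>F	a
ndhB	737	246	cCa>cTa	P>L	a
ndhB	830	277	tCa>tTa	S>L	a
ndhB	836	279	tCa>tTa	S>L	a
ndhB	1481	494	cCa>cTa	P>L	a
ndhD	878	293	tCa>tTa	S>L	a
ndhF	62	21	tCa>tTa	S>L	
ndhF	1487	496	aCg>aTg	T>M	
petB	662	221	cCa>cTa	P>L	
rpoC2	2009	670	cCa>cTa	P>L	
rpoC2	2030	677	cCa>cTa	P>L	
rpoC2	2158	720	Ccc>Tcc	P>S	
rpoC2	3002	1001	cCg>cTg	P>L	
rpoC2	4031	1344	tCg>tTg	S>L	
rpl2	62	21	aCt>aTt	T>I	
rpl20	308	103	tCa>tTa	S>L	
rpoA	1009	337	Ctc>Ttc	L>F	
rpoB	467	156	tCg>tTg	S>L	a
rpoB	545	182	tCa>tTa	S>L	a
rpoB	560	187	tCg>tTg	S>L	a
rpoB	617	206	cCg>cTg	P>L	b
rps8	182	61	tCa>tTa	S>L	
ycf3	44	15	tCc>tTc	S>F	
ycf3	191	64	aCg>aTg	T>M	
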