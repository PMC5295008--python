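gene	site	aa_pos	aa_pos_alias	edited_codon	aa_conversion	Ae_tauschii	H_vulgare	L_perenne	O_sativa	S_officinarum	Z_mays
matK	1	420	421	Cat	H>Y	+	+	+a	+		
rpoB	1	156		tCa	S>L	+	+	+a	+a	+	+
rpoB	2	182		tCa	S>L	+	+	+a	+a	+	+
rpoB	3	187		tCg	S>L	+	+	+a	+a	+	+
rpoB	4	206		cCg	P>L	+	-	-	-	-	+
rps14	1	27		tCa	S>L	(-)		(-)	+	+a	+
atpA	1	383		tCa	S>L	+		+	+	+	+
ycf3	1	15		tCc	S>F	+		+	(-)	-	+
ycf3	2	62	64	aCg	T>M	+		+	+a	+	+a
ndhG	1	116		cCa	P>L	+a		+	+		(-)
rpl20	1	103		tCa	S>L	+		+a	(-)	+a	+
psbL	1	37		ttC	F>F	+a		+a	(-)		
rps8	1	61		tCa	S>L	+		+	+	+	+
rpl2	1	1		aCg	T>M	(-)	+	+a	+a	+a	+
ndhB	1	50		tCa	S>L	+	+	+	(-)	(-)	(-)
ndhB	2	156		cCa	P>L	+	+	+	+	+	+
ndhB	3	196		Cat	H>Y	+	+	+	+	+	+
ndhB	4	204		tCa	S>L	+	+	+	+a	+	+
ndhB	5	235		tCc	S>F	+	+	+	+	(-)	(-)
ndhB	6	246		cCa	P>L	+	+	+	+	+	+
ndhB	7	277		tCa	S>L	+	+	+	+	+	+
ndhB	8	279		tCa	S>L	+	+	+	+	(-)	(-)
ndhB	9	494		cCa	P>L	+	+	+	+a	+	+
ndhF	1	21		tCa	S>L	+		+	+	+a	+
ndhD	1	295	293	tCa	S>L	+	+	+a	+	+	+
ndhA	1	17		tCa	S>L	(-)	+	+	(-)	+	+
ndhA	2	158		tCa	S>L	+	+	+	+	+	+
ndhA	3	188		tCa	S>L	+	+	+	+	+	+
ndhA	4	357		tCc	S>F	+	+	(-)	+	+	+
ndhK	1	2		gtC	V>V	-		+			
ndhK	2	43	42	cCa	P>L	+		+			
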