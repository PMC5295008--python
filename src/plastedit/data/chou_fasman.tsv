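# Chou-Fasman conformational propensities (x100 scale; > 100 means former)
# and positional bend frequencies f(i)..f(i+3) from the classic tables.
residue	p_helix	p_sheet	p_turn	f0	f1	f2	f3
A	142	83	66	0.060	0.076	0.035	0.058
R	98	93	95	0.070	0.106	0.099	0.085
N	67	89	156	0.161	0.083	0.191	0.091
D	101	54	146	0.147	0.110	0.179	0.081
C	70	119	119	0.149	0.050	0.117	0.128
E	151	37	74	0.056	0.060	0.077	0.064
Q	111	110	98	0.074	0.098	0.037	0.098
G	57	75	156	0.102	0.085	0.190	0.152
H	100	87	95	0.140	0.047	0.093	0.054
I	108	160	47	0.043	0.034	0.013	0.056
L	121	130	59	0.061	0.025	0.036	0.070
K	114	74	101	0.055	0.115	0.072	0.095
M	145	105	60	0.068	0.082	0.014	0.055
F	113	138	60	0.059	0.041	0.065	0.065
P	57	55	152	0.102	0.301	0.034	0.068
S	77	75	143	0.120	0.139	0.125	0.106
T	83	119	96	0.086	0.108	0.065	0.079
W	108	137	96	0.077	0.013	0.064	0.167
Y	69	147	114	0.082	0.065	0.114	0.125
V	106	170	50	0.062	0.048	0.028	0.053
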