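peptide	protein	s1	s2	s3	s4	s5	s6	s7	s8
A[M]AGKDLR	PUP1	100	105	95	102	2000	2100	1900	2040
C[M]TTVEK	PUP2	50	52	49	51	820	860	800	830
D[M]PLLHK	PUP3	200	210	190	205	600	630	580	615
E[M]FNWYR	PDOWN1	400	420	380	410	100	105	95	102
F[M]GHIWR	PNS1	100	103	98	101	110	108	112	109
G[M]ADEPK	PNS2	90	110	95	105	300	30	600	20
H[M]TSVWK	PNA1	100	102	98	101	250	260
I[M]QQRTK	PNS3	120	118	122	121	119	121	120	122
K[M]VVDSR	PNS4	80	82	79	81	83	80	82	81
L[M]EEGFK	PNS5	500	510	490	505	495	505	515	500
N[M]WHATK	PNS6	60	61	59	62	58	62	60	61
P[M]YYCLR	PNS7	900	910	890	905	920	880	900	910
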