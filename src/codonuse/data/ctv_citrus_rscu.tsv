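aa	codon	Ca-CTV	Cr-CTV	Cs-CTV	C.aurantifolia	C.reticulata	C.sinensis
Phe	UUU	1.11	1.14	1.01	1.20	1.08	1.24
Phe	UUC	0.89	0.86	0.99	0.80	0.92	0.76
Leu	UUA	1.54	1.40	1.47	0.95	0.88	0.87
Leu	UUG	2.54	2.70	2.62	1.49	1.52	1.56
Leu	CUU	1.13	1.12	1.13	1.40	1.28	1.48
Leu	CUC	0.01	0.01	0.01	1.16	0.91	0.71
Leu	CUA	0.24	0.26	0.31	0.48	0.43	0.57
Leu	CUG	0.54	0.50	0.46	0.52	0.98	0.82
Ile	AUU	0.91	0.81	0.80	1.39	1.48	1.51
Ile	AUC	0.50	0.59	0.55	0.93	0.90	0.71
Ile	AUA	1.59	1.60	1.65	0.68	0.63	0.77
Val	GUU	1.34	1.37	1.35	1.57	1.34	1.65
Val	GUC	1.00	1.01	1.07	0.90	0.84	0.63
Val	GUA	0.51	0.48	0.37	0.55	0.54	0.66
Val	GUG	1.15	1.13	1.21	0.98	1.29	1.06
Pro	CCU	1.49	1.44	1.38	1.84	1.54	1.50
Pro	CCC	0.03	0.04	0.06	0.66	0.69	0.58
Pro	CCA	0.37	0.22	0.28	1.18	1.29	1.46
Pro	CCG	2.11	2.30	2.28	0.32	0.49	0.45
Thr	ACU	1.72	1.86	1.84	1.20	1.49	1.48
Thr	ACC	0.89	0.78	0.77	0.99	0.84	0.75
Thr	ACA	0.66	0.64	0.65	1.34	1.21	1.36
Thr	ACG	0.73	0.72	0.73	0.47	0.45	0.42
Ala	GCU	1.90	1.86	1.85	1.88	1.41	1.65
Ala	GCC	0.76	0.82	0.87	1.08	1.01	0.69
Ala	GCA	0.88	0.84	0.83	0.78	1.13	1.34
Ala	GCG	0.47	0.48	0.44	0.25	0.46	0.32
Tyr	UAU	1.29	1.28	1.29	0.94	1.03	1.23
Tyr	UAC	0.71	0.72	0.71	1.06	0.97	0.77
Ser	UCU	2.27	2.42	2.42	1.68	1.41	1.56
Ser	UCC	0.71	0.56	0.53	0.96	0.84	0.72
Ser	UCA	0.75	0.84	0.81	1.20	1.33	1.45
Ser	UCG	0.38	0.32	0.30	0.48	0.69	0.42
Ser	AGU	1.45	1.57	1.53	0.80	0.87	1.07
Ser	AGC	0.44	0.29	0.41	0.89	0.85	0.77
Arg	AGA	1.18	1.09	1.12	2.38	1.84	1.98
Arg	AGG	0.69	0.75	0.76	0.83	1.29	1.49
Arg	CGU	2.18	2.21	2.21	0.89	0.91	0.79
Arg	CGC	0.55	0.49	0.53	0.49	0.70	0.48
Arg	CGA	0.95	1.01	0.92	0.89	0.69	0.70
Arg	CGG	0.45	0.44	0.47	0.52	0.56	0.55
Cys	UGU	2.00	1.95	1.95	0.97	0.76	1.13
Cys	UGC	0.00	0.05	0.05	1.03	1.24	0.87
His	CAU	0.59	0.62	0.61	1.15	1.05	1.32
His	CAC	1.41	1.38	1.39	0.85	0.95	0.68
Gln	CAA	1.01	1.04	1.02	1.02	1.00	1.10
Gln	CAG	0.99	0.96	0.98	0.98	1.00	0.90
Asn	AAU	0.52	0.59	0.59	0.83	1.11	1.30
Asn	AAC	1.48	1.41	1.41	1.17	0.89	0.70
Lys	AAA	0.84	0.84	0.79	1.05	0.93	0.99
Lys	AAG	1.16	1.16	1.21	0.95	1.07	1.01
Asp	GAU	1.16	1.17	1.16	1.29	1.33	1.42
Asp	GAC	0.84	0.83	0.84	0.71	0.67	0.58
Glu	GAA	1.32	1.26	1.35	1.04	0.99	1.10
Glu	GAG	0.68	0.74	0.65	0.96	1.01	0.90
Gly	GGU	1.62	1.54	1.48	1.26	1.09	1.20
Gly	GGC	0.65	0.73	0.75	1.11	0.98	0.73
Gly	GGA	0.76	0.74	0.77	1.13	1.21	1.29
Gly	GGG	0.97	1.00	0.99	0.50	0.71	0.77
Trp	UGG	1.00	1.00	1.00	1.00	1.00	1.00
Met	AUG	1.00	1.00	1.00	1.00	1.00	1.00
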