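# Staphylococcal nuclease: experimental pKa values. SYNTHETIC RECONSTRUCTION
# from the primary NMR literature (carboxylic acids from the hyperstable
# variant measurements, plus His-46/His-121); the exact residue subset used
# in published st-CpHMD benchmarks is not fully recoverable, so aggregate
# statistics computed from this table can differ from published ones.
# See docs/methods.md.
residue	residue_type	pka_exp
ASP19	Asp	2.21
ASP21	Asp	6.54
ASP40	Asp	3.87
ASP95	Asp	2.16
GLU10	Glu	2.82
GLU43	Glu	4.32
GLU52	Glu	3.93
GLU57	Glu	3.49
GLU67	Glu	3.76
GLU73	Glu	3.31
GLU75	Glu	3.26
GLU101	Glu	3.81
GLU122	Glu	3.89
GLU129	Glu	3.75
GLU135	Glu	3.76
HIS46	His	6.5
HIS121	His	5.30
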