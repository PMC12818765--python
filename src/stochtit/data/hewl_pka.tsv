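# Hen egg-white lysozyme: experimental pKa values compiled from the NMR
# literature (18 residues; tyrosines omitted as their pKa lies outside the
# usual titrated pH range). See docs/methods.md for provenance.
residue	residue_type	pka_exp
NTR	NTr	7.9
LYS1	Lys	10.8
GLU7	Glu	2.85
LYS13	Lys	10.5
HIS15	His	5.36
ASP18	Asp	2.66
LYS33	Lys	10.6
GLU35	Glu	6.2
ASP48	Asp	1.6
ASP52	Asp	3.68
ASP66	Asp	0.9
ASP87	Asp	2.07
LYS96	Lys	10.8
LYS97	Lys	10.3
ASP101	Asp	4.09
LYS116	Lys	10.4
ASP119	Asp	3.2
CTR	CTr	2.75
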