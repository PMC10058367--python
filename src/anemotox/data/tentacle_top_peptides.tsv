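row	TRINITY	Name	Peptide	Mucus Sample Area	Tentacle Sample Area
t01	TRINITY_DN1213	-	DCRGKHCQTGPFGD	9.06E+09	4.84E+08
t02	TRINITY_DN282	Histone H2B	LPGELAKHAVSEGTKAVTKYTSSK	-	3.99E+08
t03	TRINITY_DN58641	-	TLASSIQCVGKCKIKTSSGQCRTDLRCMLANKGAS	1.7E+09	3.88E+08
t04	TRINITY_DN3037	-	NPPYEEILEPAFFHIR	-	2.61E+08
t05	TRINITY_DN10521	-	APPDTSILDKLGKL	7.26E+06	2.13E+08
t06	TRINITY_DN12562	-	DEAGLLKYKTAAGAALVNERLKNLAERY	-	1.81E+08
t07	TRINITY_DN3037	-	QPPFLGGPAYFHIR	-	1.52E+08
t08	TRINITY_DN282	Histone H2B	LLLPGELAKHAVSEGTKAVTKYTSSK	8.66E+06	1.52E+08
t09	TRINITY_DN25490	U-actitoxin-Aeq6a	KERCDLLGDPCVKG	-	1.51E+08
t10	TRINITY_DN1828	-	AAAYVCDVARNLDCSAH	-	1.43E+08
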