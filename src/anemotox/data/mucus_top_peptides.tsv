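row	TRINITY	Name	Peptide	Mucus Sample Area	Tentacle Sample Area
m01	TRINITY_DN1213	-	DCRGKHCQTGPFGD	9.06E+09	4.84E+08
m02	TRINITY_DN58641	-	TLASSIQCVGKCKIKTSSGQCRTDLRCMLANKGAS	1.70E+09	3.88E+08
m03	TRINITY_DN14686	U-actitoxin-Bcs2a	GLPCDCHGHTGTYWLNYYSKCPKGYGYTGRCRYLVGSCCYK	1.32E+09	-
m04	TRINITY_DN3092	-	MATSCRKCKPGYGCWAVPCPKR	1.09E+09	-
m05	TRINITY_DN557	Lamin-A	EELSFKRSVYDKE	5.92E+08	-
m06	TRINITY_DN1213	-	DCRGKHCQTGPF	3.56E+08	1.38E+06
m07	TRINITY_DN14686	U-actitoxin-Bcs2a	GLPCDCHGHTGTY	2.59E+08	-
m08	TRINITY_DN3092	-	MATSCRKCKPGYGCWAVPCPKR	2.16E+08	-
m09	TRINITY_DN3092	-	ATSCRKCKPGYGCWAVPCPKR	1.71E+08	-
m10	TRINITY_DN14686	U-actitoxin-Bcs2a	WLNYYSKCPKGYGYTGRCRYLVGSCCYK	1.68E+08	-
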