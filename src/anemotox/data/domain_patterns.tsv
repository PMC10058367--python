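name	pattern	note	low_confidence
ShKT	C-x(3,8)-C-x(3,8)-C-x(4,12)-C-x(2,12)-C-x(2,10)-C	six-cysteine spacing of ShK-like potassium channel toxin domains; pattern-scan (PFAM-like) approximation
Kunitz	C-x(6,10)-C-x(13,17)-C-x(5,9)-C-x(10,14)-C-x(2,5)-C	venom Kunitz-type protease-inhibitor fold cysteine spacing; pattern-scan (PFAM-like) approximation
Kazal	C-x(5,9)-C-x(5,7)-C-x(5,8)-C-x(10,15)-C-x(1,4)-C	Kazal-type serine protease inhibitor domain cysteine spacing; pattern-scan (PFAM-like) approximation
BDS_defensin	C-x(1,3)-C-x(10,16)-C-x(6,12)-C-x(4,8)-C-x(0,1)-C	sea anemone type 3 (BDS) potassium channel toxin / defensin-fold spacing; pattern-scan (PFAM-like) approximation
EGF	C-x(3,14)-C-x(3,7)-C-x(1,6)-C-x(1,3)-C-x(2,10)-C	EGF-like domain cysteine spacing; pattern-scan (PFAM-like) approximation
F5/8C	C-x(60,120)-C	coagulation factor 5/8 C-terminal (discoidin) domain; not cysteine-stabilised, spacing only weakly informative	true
Lectin_C	C-x(14,30)-C-x(20,50)-C-x(18,40)-C	C-type lectin domain partial cysteine spacing	true
SRCR	C-x(7,16)-C-x(10,30)-C-x(4,15)-C-x(8,20)-C	scavenger receptor cysteine-rich domain partial spacing	true
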