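family	category
Sea anemone type 3 (BDS) potassium channel toxin	neurotoxin
Venom Kunitz type. Sea anemone type 2 potassium channel toxin.	neurotoxin
Sea anemone type 1 potassium channel toxin	neurotoxin
Anemone neurotoxin	neurotoxin
Kazal-type serine protease inhibitor domain	neurotoxin
ShK domain-like	neurotoxin
Sodium channel inhibitor	neurotoxin
Small cysteine-rich protein	neurotoxin
Phospholipase A2	mixed-function enzyme
Astacin	mixed-function enzyme
Cystatin domain	mixed-function enzyme
Venom proteinase	mixed-function enzyme
Actinoporin	membrane-active
Jellyfish toxin	membrane-active
EGF-domain peptide	unknown
Sea anemone 8 toxin	unknown
Acrohargin	unknown
F5/8 C domain	unknown
Lectin C-type domain	unknown
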