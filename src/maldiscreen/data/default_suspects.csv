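name,cas,formula,class,pos_species,neg_species
TPhP,115-86-6,C18H15O4P,OPFR,M+H;M+K;M+Na,M-C6H5
BDP,5945-33-5,C39H34O8P2,OPFR,M+H;M+K;M+Na,M-C6H5
RDP,57583-54-7,C30H24O8P2,OPFR,M+H;M+K;M+Na,M-C6H5
TCEP,115-96-8,C6H12Cl3O4P,OPFR,M+H;M+K;M+Na,
TCP,1330-78-5,C21H21O4P,OPFR,M+H;M+K;M+Na,
TBBPA,79-94-7,C15H12Br4O2,BFR,,M-H
TTBP-TAZ,25713-60-4,C21H6Br9N3O3,BFR,,M-C6H2Br3-H
"2,4,6-TBP",118-79-6,C6H3Br3O,BFR,,M-H
ATE,3278-89-5,C9H7Br3O,BFR,,M-C3H5
BDE209,1163-19-5,C12Br10O,BFR,,M-H
Irgafos 168,31570-04-4,C42H63O3P,antioxidant,M+H;M+K;M+Na,M-C14H21+O
Irganox 1076,2082-79-3,C35H62O3,antioxidant,M+H;M+K;M+Na,
BHT-COOH,1421-49-4,C15H22O3,antioxidant,,M-H
BPA,80-05-7,C15H16O2,monomer,M-CH3;M+H;M+K;M+Na,M-H
Benzyl benzoate,120-51-4,C14H12O2,fragrance,M+H;M+K;M+Na,
DEHP,117-81-7,C24H38O4,phthalate,M+H;M+K;M+Na,
DNOP,117-84-0,C24H38O4,phthalate,M+H;M+K;M+Na,
DBP,84-74-2,C16H22O4,phthalate,M+H;M+K;M+Na,
BBP,85-68-7,C19H20O4,phthalate,M+H;M+K;M+Na,
DEP,84-66-2,C12H14O4,phthalate,M+H;M+K;M+Na,
DMP,131-11-3,C10H10O4,phthalate,M+H;M+K;M+Na,
Tinuvin 770,52829-07-9,C28H52N2O4,UV-stabilizer,M+H,
Uvitex OB,7128-64-5,C26H26N2O2S,UV-filter,M,
Sulisobenzone,4065-45-6,C14H12O6S,UV-filter,,M-H
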