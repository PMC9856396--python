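gene	cls
CDH1	E
EPCAM	E
KRT8	E
KRT18	E
CLDN4	E
CLDN7	E
DSP	E
OCLN	E
MUC1	E
ESRP1	E
VIM	M
FN1	M
ZEB1	M
ZEB2	M
SNAI1	M
SNAI2	M
TWIST1	M
CDH2	M
MMP2	M
S100A4	M
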