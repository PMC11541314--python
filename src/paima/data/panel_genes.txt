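# PAIma panel: 128 pharmacogenes curated for pain, anti-inflammatory and
# immunomodulating drug pathways. One gene symbol per line.
ABCB1
ABCC2
ABCC3
ABCC4
ABCG2
AKR1B1
AKR1C3
AMACR
ATF2
ATF3
BATF
CES1
CES2
CNR1
CNR2
CYP1A2
CYP1A1
CYP2A6
CYP2C18
CYP2B6
CYP2C19
CYP2D6
CYP2C9
CYP2C8
CYP2E1
CYP3A
CYP3A4
CYP3A7
CYP3A5
FAAH
FKBP1A
FOS
FOSB
FOSL1
FOSL2
GSTA1
GSTM1
GSTP1
GSTT1
HPGDS
IL2
IMPDH1
IMPDH2
JUN
JUNB
JDP2
JUND
MAFB
MAFA
MAFG
MAFF
MAFK
MAF
MAP2K4
MAP2K3
MAP2K6
MAP3K1
MAP2K7
MAP3K7
MAPK8
MAP3K11
MAPK14
NFATC2
NFATC1
NFATC4
NFKB2
NFKB1
NOS1
NOS2
NOS3
NRL
PLA2G2A
PLA2G4A
PPP3CA
PPIA
PPP3CC
PPP3CB
PPP3R1
PTGDR
PPP3R2
PTGDR2
PTGER1
PTGDS
PTGER2
PTGER4
PTGER3
PTGES
PTGES3
PTGES2
PTGIR
PTGFR
PTGIS
PTGS2
PTGS1
REL
RELB
RELA
S1PR1
S1PR3
S1PR5
SLC22A1
SLC22A11
SLC22A6
SLC22A7
SLC22A8
SLC22A9
SLCO1B1
SLCO1B3
SLCO2B1
SULT1A1
SULT1A3
SULT1A4
SULT1E1
SULT2A1
TBXA2R
TBXAS1
TGFB1
UGT1A10
UGT1A1
UGT1A3
UGT1A7
UGT1A6
UGT1A8
UGT2B15
UGT1A9
UGT2B17
UGT2B7
UGT2B4
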