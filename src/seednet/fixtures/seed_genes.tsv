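ABCB1
ACE
ADCY3
ADCY6
ADCY9
ADK
AKT1
APAF1
APOE
ARNTL
ARRB1
ATP6V1B2
AVPR1B
BDNF
CACNA1A
CACNA1C
CACNA1D
CACNA1E
CACNA1S
CACNA2D2
CACNA2D4
CACNB2
CHST11
CNR1
COMT
CREB1
CRHR1
CRHR2
CRY1
CTLA4
CYP2B6
CYP2C19
CYP2D6
DIO1
DNAJB2
DRD1
DRD4
EGF
EHD3
EHHADH
ESR1
FKBP4
FKBP5
GABBR2
GABRA4
GABRB3
GABRD
GABRG2
GHRHR
GNB1
GNB3
GPX5
GRIA1
GRIA2
GRIA4
GRIK1
GRIK4
GRIN2A
GRIN2B
GRM7
GRM8
GSK3B
HCRTR1
HOMER1
HSD3B1
HTR1A
HTR1B
HTR2A
HTR2C
HTR4
HTR6
IDO1
IDO2
IKBKE
IL10
IL1B
IL33
IL6
ITPR1
KCNK2
MAGI1
MAOA
MAP3K13
MYBPC3
NAMPT
NDUFV2
NFKB1
NGF
NPAS2
NPY
NR1D1
NR3C1
NRG1
NT5C2
NTRK2
NTRK3
OPRM1
P2RX7
PCLO
PDE11A
PDE1C
PDE2A
PDE4B
PDE5A
PDE6C
PLD1
POMC
PRKAG2
PRKCG
PTPRR
RPS6KB1
SHC3
SIRT1
SLC1A2
SLC6A1
SLC6A3
SLC6A4
SNAP25
SPI1
STAT1
TBX21
TGFB1
TNF
TP53
TPH1
TPH2
UGT2A1
UGT2A2
UGT2B4
VIPR2
XDH
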