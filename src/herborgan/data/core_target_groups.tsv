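TNF	bone marrow
MAPK14	bone marrow
CTNNB1	bone marrow
HSP90AA1	bone marrow
CREB1	bone marrow
NFKB1	bone marrow
NR3C1	bone marrow
TP53	bone marrow
PTPN11	bone marrow
STAT1	bone marrow
MYC	bone marrow
FOS	bone marrow
JAK2	bone marrow
JUN	bone marrow
SRC	lymphoid tissue
MAPK8	lymphoid tissue
ESR1	lymphoid tissue
LYN	lymphoid tissue
EGFR	lymphoid tissue
MAPK11	lymphoid tissue
RELA	lymphoid tissue
CASP8	lymphoid tissue
CASP3	lymphoid tissue
NCOA1	whole blood
RXRA	whole blood
MAPK1	whole blood
PRKACA	whole blood
IL1B	smooth muscle
CDKN1A	smooth muscle
HIF1A	smooth muscle
IL6	smooth muscle
VEGFA	prostate
AR	prostate
AKT1	prostate
CCND1	prostate
EDN1	lung
MAPK3	lung
STAT3	lung
RB1	cardiac myocytes
IL10	cardiac myocytes
SMAD3	cardiac myocytes
CAV1	thyroid
PTK2	thyroid
IRS1	thyroid
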