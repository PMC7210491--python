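gene_symbol	category
ALK	mandatory
BRAF	mandatory
BRCA1	mandatory
BRCA2	mandatory
EGFR	mandatory
HER2	mandatory
IDH1	mandatory
IDH2	mandatory
KIT	mandatory
KRAS	mandatory
MYC	mandatory
MYCN	mandatory
NRAS	mandatory
PDGFRA	mandatory
ABL1	additional
AKT1	additional
AKT3	additional
APC	additional
AR	additional
ATM	additional
AXL	additional
CCND1	additional
CDH1	additional
CDK4	additional
CDK6	additional
CDKN2A	additional
CEBPA	additional
CSF1R	additional
CTNNB1	additional
DDR2	additional
ERBB2	additional
ERBB3	additional
ERBB4	additional
ERG	additional
ESR1	additional
ETV1	additional
ETV4	additional
ETV5	additional
EZH2	additional
FANCA	additional
FANCC	additional
FANCF	additional
FANCG	additional
FBXW7	additional
FGFR1	additional
FGFR2	additional
FGFR3	additional
FGFR4	additional
FLT3	additional
FOXL2	additional
GNA11	additional
GNAQ	additional
GNAS	additional
HNF1A	additional
JAK1	additional
JAK2	additional
JAK3	additional
KDR	additional
MAP2K1	additional
MAP2K2	additional
MAP2K4	additional
MET	additional
MLH1	additional
MTOR	additional
NOTCH1	additional
NPM1	additional
NTRK1	additional
NTRK2	additional
NTRK3	additional
PIK3CA	additional
PIKR1	additional
PPARG	additional
PTEN	additional
PTPN11	additional
RAF1	additional
RB1	additional
RET	additional
ROS1	additional
RUNX1	additional
SMAD4	additional
SMARCB1	additional
SMO	additional
SRC	additional
STK11	additional
TP53	additional
VHL	additional
WT1	additional
NRG1	additional
ALK	fusion
ROS1	fusion
RET	fusion
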