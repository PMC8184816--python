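symbol	source
ACOT7	DISEASES
HES2	DISEASES
UBIAD1	DISEASES
MTHFR	DISEASES
SCP2	DISEASES
CTH	DISEASES
F3	DISEASES
SARS	DISEASES
CRP	DISEASES
LIN9	DISEASES
MTR	DISEASES
THUMPD2	DISEASES
TXNDC9	DISEASES
LRP2	DISEASES
HAT1	DISEASES
METAP1D	DISEASES
CASR	DISEASES
ALDH1L1	DISEASES
TF	DISEASES
CP	DISEASES
LXN	DISEASES
TFRC	DISEASES
CSN1S1	DISEASES
HTN3	DISEASES
ALB	DISEASES
METAP1	DISEASES
GYPA	DISEASES
PRELID2	DISEASES
HRH2	DISEASES
ADAMTS2	DISEASES
PGC	DISEASES
GNMT	DISEASES
LMBRD1	DISEASES
PON1	DISEASES
GGH	DISEASES
FPGS	DISEASES
SLC27A4	DISEASES
TRDMT1	DISEASES
PANK1	DISEASES
PNLIP	DISEASES
IFITM2	DISEASES
HBE1	DISEASES
GIF	DISEASES
MS4A3	DISEASES
PGA3	DISEASES
PGA4	DISEASES
FADS1	DISEASES
FTH1	DISEASES
CBL	DISEASES
CD4	DISEASES
CS	DISEASES
SHMT2	DISEASES
METAP2	DISEASES
MVK	DISEASES
SDS	DISEASES
ATP12A	DISEASES
CLYBL	DISEASES
ATP4B	DISEASES
AMN	DISEASES
TGM5	DISEASES
DUT	DISEASES
NDUFAB1	DISEASES
HP	DISEASES
HPR	DISEASES
PEMT	DISEASES
TNFAIP1	DISEASES
GAST	DISEASES
ACLY	DISEASES
MMD	DISEASES
TYMS	DISEASES
MBP	DISEASES
SLC27A1	DISEASES
ATP4A	DISEASES
CD79A	DISEASES
FTL	DISEASES
NTSR1	DISEASES
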