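symbol	group	cc_category	tr_category	receptor_class	pathway_ids	provenance
ETS1	TR	none	none	none	1	curated
JUN	TR	none	homeostatic	transcription_factor	1	curated
FOXO1	TR	none	none	none	2	curated
FOXO3	TR	none	none	none	2	curated
RBPJ	TR	none	none	none	3	curated
NFKB1	TR	none	none	none	4	curated
NFKB2	TR	none	none	none	4	curated
REL	TR	none	none	none	4	curated
RELA	TR	none	none	none	4	curated
RELB	TR	none	none	none	4	curated
STAT1	TR	none	none	none	5	curated
STAT3	TR	none	none	none	5	curated
ARNT	TR	none	none	none	6	curated
EPAS1	TR	none	ec_specific	transcription_factor	6	curated
HIF1A	TR	none	ec_specific	transcription_factor	6	curated
NOTCH1	TR	none	none	none	3	curated
NOTCH2	TR	none	none	none	3	curated
NOTCH3	TR	none	none	ec_surface	3	curated
NOTCH4	TR	none	none	none	3	curated
SOX2	TR	none	none	none		curated
MYC	TR	none	none	none		curated
KLF4	TR	none	none	none		curated
POU5F1	TR	none	none	none		curated
EGR1	TR	none	none	none		inferred
ID1	TR	none	none	none		inferred
ETS2	TR	none	none	none		inferred
DLL1	GFR	none	none	none	3	curated
DLL3	GFR	none	none	none	3	curated
DLL4	GFR	none	none	none	3	curated
JAG1	GFR	none	none	secreted_factor	3	curated
JAG2	GFR	none	none	none	3	curated
FIGF	GFR	none	none	none	6	curated
FLT1	GFR	none	none	ec_surface	6	curated
FLT4	GFR	none	none	none	6	curated
KDR	GFR	none	none	ec_surface	6	curated
NRP1	GFR	none	none	ec_surface	6	curated
NRP2	GFR	none	none	ec_surface	6	curated
PGF	GFR	none	none	secreted_factor	6	curated
VEGFA	GFR	none	none	secreted_factor	6	curated
VEGFB	GFR	none	none	none	6	curated
VEGFC	GFR	none	none	none	6	curated
ANGPT1	GFR	none	none	none	7	curated
ANGPT2	GFR	none	none	secreted_factor	7	curated
ANGPTL3	GFR	none	none	none	7	curated
ANGPTL4	GFR	none	none	secreted_factor	7	curated
TEK	GFR	none	none	ec_surface	7	curated
TIE1	GFR	none	none	ec_surface	7	curated
CD34	GFR	none	none	none		curated
KIT	GFR	none	none	none		curated
FGF1	GFR	none	none	none		inferred
FGF2	GFR	none	none	none		inferred
FGFR1	GFR	none	none	none		inferred
FGFR2	GFR	none	none	none		inferred
FGFR3	GFR	none	none	none		inferred
HGF	GFR	none	none	none		inferred
MET	GFR	none	none	none		inferred
PDGFA	GFR	none	none	none		inferred
PDGFB	GFR	none	none	none		inferred
PDGFC	GFR	none	none	none		inferred
PDGFD	GFR	none	none	none		inferred
PDGFRA	GFR	none	none	none		inferred
PDGFRB	GFR	none	none	none		inferred
EGF	GFR	none	none	none		inferred
EGFR	GFR	none	none	none		inferred
IGF1	GFR	none	none	none		inferred
IGF1R	GFR	none	none	none		inferred
IGF2	GFR	none	none	none		inferred
TGFA	GFR	none	none	none		inferred
TGFB1	GFR	none	none	none		inferred
TGFB2	GFR	none	none	none		inferred
TGFBR1	GFR	none	none	none		inferred
TGFBR2	GFR	none	none	none		inferred
ENG	GFR	none	none	none		inferred
ACVRL1	GFR	none	none	none		inferred
NRG1	GFR	none	none	none		inferred
ERBB2	GFR	none	none	none		inferred
HBEGF	GFR	none	none	none		inferred
CTGF	GFR	none	none	none		inferred
CYR61	GFR	none	none	none		inferred
EFNA1	GFR	none	none	none		inferred
EFNB2	GFR	none	none	none		inferred
EPHA2	GFR	none	none	none		inferred
EPHB4	GFR	none	none	none		inferred
ESM1	GFR	none	none	none		inferred
BMP2	GFR	none	none	none		inferred
BMP4	GFR	none	none	none		inferred
BMPR2	GFR	none	none	none		inferred
S1PR1	GFR	none	none	none		inferred
SEMA3A	GFR	none	none	none		inferred
PLXND1	GFR	none	none	none		inferred
CCL2	CC	pro	none	none		curated
CCL5	CC	pro	none	none		curated
IL6	CC	pro	none	none		curated
IL15	CC	pro	none	none		curated
CXCL1	CC	pro	none	none		inferred
CXCL2	CC	pro	none	none		inferred
CXCL3	CC	pro	none	none		inferred
CXCL5	CC	pro	none	none		inferred
CXCL6	CC	pro	none	none		inferred
CXCL8	CC	pro	none	none		inferred
CXCL12	CC	pro	none	none		inferred
IL1B	CC	pro	none	none		inferred
TNF	CC	pro	none	none		inferred
IL17A	CC	pro	none	none		inferred
CXCL9	CC	anti	none	none		curated
CXCL10	CC	anti	none	none		inferred
CXCL11	CC	anti	none	none		curated
CXCL13	CC	anti	none	none		inferred
CXCL14	CC	anti	none	none		curated
PF4	CC	anti	none	none		curated
IL12A	CC	anti	none	none		inferred
IL18	CC	bi	none	none		curated
CXCL16	CC	bi	none	none		curated
IL4	CC	bi	none	none		inferred
IL10	CC	bi	none	none		inferred
IL13	CC	bi	none	none		inferred
CCL11	CC	bi	none	none		inferred
MAPK1	PI	none	none	none	1	curated
MAPK8	PI	none	none	none	1	curated
MAPK14	PI	none	none	none	1	curated
MAP4K4	PI	none	none	none	1	curated
AKT1	PI	none	none	none	2	curated
PIK3CA	PI	none	none	none	2	curated
PIK3CB	PI	none	none	none	2	curated
PIK3CD	PI	none	none	none	2	curated
PIK3CG	PI	none	none	none	2	curated
PTEN	PI	none	none	none	2	curated
CISH	PI	none	none	none	5	curated
JAK2	PI	none	none	none	5	curated
EGLN1	PI	none	none	none	6	curated
MMP1	PI	none	none	none		inferred
MMP2	PI	none	none	none		inferred
MMP3	PI	none	none	none		inferred
MMP7	PI	none	none	none		inferred
MMP9	PI	none	none	none		inferred
MMP14	PI	none	none	none		inferred
TIMP1	PI	none	none	none		inferred
TIMP2	PI	none	none	none		inferred
TIMP3	PI	none	none	none		inferred
TIMP4	PI	none	none	none		inferred
PLAU	PI	none	none	none		inferred
PLAT	PI	none	none	none		inferred
PLAUR	PI	none	none	none		inferred
PLG	PI	none	none	none		inferred
SERPINE1	PI	none	none	none		inferred
SERPINF1	PI	none	none	none		inferred
ADAM10	PI	none	none	none		inferred
ADAM17	PI	none	none	none		inferred
ADAMTS1	PI	none	none	none		inferred
ADAMTS4	PI	none	none	none		inferred
CTSB	PI	none	none	none		inferred
CTSD	PI	none	none	none		inferred
CTSL	PI	none	none	none		inferred
ELANE	PI	none	none	none		inferred
F2	PI	none	none	none		inferred
F3	PI	none	none	none		inferred
THBS1	PI	none	none	none		inferred
THBS2	PI	none	none	none		inferred
ANG	PI	none	none	none		inferred
LEP	PI	none	none	none		inferred
COL18A1	PI	none	none	none		inferred
SERPINB5	PI	none	none	none		inferred
HPSE	PI	none	none	none		inferred
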