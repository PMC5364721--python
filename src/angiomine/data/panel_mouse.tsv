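symbol	group	cc_category	tr_category	receptor_class	pathway_ids	provenance
Ets1	TR	none	none	none	1	curated
Jun	TR	none	homeostatic	transcription_factor	1	curated
Foxo1	TR	none	none	none	2	curated
Foxo3	TR	none	none	none	2	curated
Rbpj	TR	none	none	none	3	curated
Nfkb1	TR	none	none	none	4	curated
Nfkb2	TR	none	none	none	4	curated
Rel	TR	none	none	none	4	curated
Rela	TR	none	none	none	4	curated
Relb	TR	none	none	none	4	curated
Stat1	TR	none	none	none	5	curated
Stat3	TR	none	none	none	5	curated
Arnt	TR	none	none	none	6	curated
Epas1	TR	none	ec_specific	transcription_factor	6	curated
Hif1a	TR	none	ec_specific	transcription_factor	6	curated
Notch1	TR	none	none	none	3	curated
Notch2	TR	none	none	none	3	curated
Notch3	TR	none	none	ec_surface	3	curated
Notch4	TR	none	none	none	3	curated
Sox2	TR	none	none	none		curated
Myc	TR	none	none	none		curated
Klf4	TR	none	none	none		curated
Pou5f1	TR	none	none	none		curated
Egr1	TR	none	none	none		inferred
Id1	TR	none	none	none		inferred
Ets2	TR	none	none	none		inferred
Dll1	GFR	none	none	none	3	curated
Dll3	GFR	none	none	none	3	curated
Dll4	GFR	none	none	none	3	curated
Jag1	GFR	none	none	secreted_factor	3	curated
Jag2	GFR	none	none	none	3	curated
Figf	GFR	none	none	none	6	curated
Flt1	GFR	none	none	ec_surface	6	curated
Flt4	GFR	none	none	none	6	curated
Kdr	GFR	none	none	ec_surface	6	curated
Nrp1	GFR	none	none	ec_surface	6	curated
Nrp2	GFR	none	none	ec_surface	6	curated
Pgf	GFR	none	none	secreted_factor	6	curated
Vegfa	GFR	none	none	secreted_factor	6	curated
Vegfb	GFR	none	none	none	6	curated
Vegfc	GFR	none	none	none	6	curated
Angpt1	GFR	none	none	none	7	curated
Angpt2	GFR	none	none	secreted_factor	7	curated
Angptl3	GFR	none	none	none	7	curated
Angptl4	GFR	none	none	secreted_factor	7	curated
Tek	GFR	none	none	ec_surface	7	curated
Tie1	GFR	none	none	ec_surface	7	curated
Cd34	GFR	none	none	none		curated
Kit	GFR	none	none	none		curated
Fgf1	GFR	none	none	none		inferred
Fgf2	GFR	none	none	none		inferred
Fgfr1	GFR	none	none	none		inferred
Fgfr2	GFR	none	none	none		inferred
Fgfr3	GFR	none	none	none		inferred
Hgf	GFR	none	none	none		inferred
Met	GFR	none	none	none		inferred
Pdgfa	GFR	none	none	none		inferred
Pdgfb	GFR	none	none	none		inferred
Pdgfc	GFR	none	none	none		inferred
Pdgfd	GFR	none	none	none		inferred
Pdgfra	GFR	none	none	none		inferred
Pdgfrb	GFR	none	none	none		inferred
Egf	GFR	none	none	none		inferred
Egfr	GFR	none	none	none		inferred
Igf1	GFR	none	none	none		inferred
Igf1r	GFR	none	none	none		inferred
Igf2	GFR	none	none	none		inferred
Tgfa	GFR	none	none	none		inferred
Tgfb1	GFR	none	none	none		inferred
Tgfb2	GFR	none	none	none		inferred
Tgfbr1	GFR	none	none	none		inferred
Tgfbr2	GFR	none	none	none		inferred
Eng	GFR	none	none	none		inferred
Acvrl1	GFR	none	none	none		inferred
Nrg1	GFR	none	none	none		inferred
Erbb2	GFR	none	none	none		inferred
Hbegf	GFR	none	none	none		inferred
Ctgf	GFR	none	none	none		inferred
Cyr61	GFR	none	none	none		inferred
Efna1	GFR	none	none	none		inferred
Efnb2	GFR	none	none	none		inferred
Epha2	GFR	none	none	none		inferred
Ephb4	GFR	none	none	none		inferred
Esm1	GFR	none	none	none		inferred
Bmp2	GFR	none	none	none		inferred
Bmp4	GFR	none	none	none		inferred
Bmpr2	GFR	none	none	none		inferred
S1pr1	GFR	none	none	none		inferred
Sema3a	GFR	none	none	none		inferred
Plxnd1	GFR	none	none	none		inferred
Ccl2	CC	pro	none	none		curated
Ccl5	CC	pro	none	none		curated
Il6	CC	pro	none	none		curated
Il15	CC	pro	none	none		curated
Cxcl1	CC	pro	none	none		inferred
Cxcl2	CC	pro	none	none		inferred
Cxcl3	CC	pro	none	none		inferred
Cxcl5	CC	pro	none	none		inferred
Cxcl6	CC	pro	none	none		inferred
Cxcl8	CC	pro	none	none		inferred
Cxcl12	CC	pro	none	none		inferred
Il1b	CC	pro	none	none		inferred
Tnf	CC	pro	none	none		inferred
Il17a	CC	pro	none	none		inferred
Cxcl9	CC	anti	none	none		curated
Cxcl10	CC	anti	none	none		inferred
Cxcl11	CC	anti	none	none		curated
Cxcl13	CC	anti	none	none		inferred
Cxcl14	CC	anti	none	none		curated
Pf4	CC	anti	none	none		curated
Il12a	CC	anti	none	none		inferred
Il18	CC	bi	none	none		curated
Cxcl16	CC	bi	none	none		curated
Il4	CC	bi	none	none		inferred
Il10	CC	bi	none	none		inferred
Il13	CC	bi	none	none		inferred
Ccl11	CC	bi	none	none		inferred
Mapk1	PI	none	none	none	1	curated
Mapk8	PI	none	none	none	1	curated
Mapk14	PI	none	none	none	1	curated
Map4k4	PI	none	none	none	1	curated
Akt1	PI	none	none	none	2	curated
Pik3ca	PI	none	none	none	2	curated
Pik3cb	PI	none	none	none	2	curated
Pik3cd	PI	none	none	none	2	curated
Pik3cg	PI	none	none	none	2	curated
Pten	PI	none	none	none	2	curated
Cish	PI	none	none	none	5	curated
Jak2	PI	none	none	none	5	curated
Egln1	PI	none	none	none	6	curated
Mmp1	PI	none	none	none		inferred
Mmp2	PI	none	none	none		inferred
Mmp3	PI	none	none	none		inferred
Mmp7	PI	none	none	none		inferred
Mmp9	PI	none	none	none		inferred
Mmp14	PI	none	none	none		inferred
Timp1	PI	none	none	none		inferred
Timp2	PI	none	none	none		inferred
Timp3	PI	none	none	none		inferred
Timp4	PI	none	none	none		inferred
Plau	PI	none	none	none		inferred
Plat	PI	none	none	none		inferred
Plaur	PI	none	none	none		inferred
Plg	PI	none	none	none		inferred
Serpine1	PI	none	none	none		inferred
Serpinf1	PI	none	none	none		inferred
Adam10	PI	none	none	none		inferred
Adam17	PI	none	none	none		inferred
Adamts1	PI	none	none	none		inferred
Adamts4	PI	none	none	none		inferred
Ctsb	PI	none	none	none		inferred
Ctsd	PI	none	none	none		inferred
Ctsl	PI	none	none	none		inferred
Elane	PI	none	none	none		inferred
F2	PI	none	none	none		inferred
F3	PI	none	none	none		inferred
Thbs1	PI	none	none	none		inferred
Thbs2	PI	none	none	none		inferred
Ang	PI	none	none	none		inferred
Lep	PI	none	none	none		inferred
Col18a1	PI	none	none	none		inferred
Serpinb5	PI	none	none	none		inferred
Hpse	PI	none	none	none		inferred
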