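id_name	description	genomes
Thioredoxin	Thioredoxin	VV,AABBDD,AA,DD,HH,Bd,Os
B3	B3 DNA binding domain	VV,AABBDD,AA,DD,HH,Os
Pkinase	Protein kinase domain	VV,AABBDD,AA,DD,HH,Bd
Pkinase_Tyr	Protein tyrosine and serine/threonine kinase	VV,AABBDD,AA,DD,HH,Bd
WRKY	WRKY DNA-binding domain	VV,AABBDD,AA,DD,HH,Bd
zf-BED	BED zinc finger	VV,AABBDD,AA,DD,HH,Bd
DDE_Tnp_4	DDE superfamily endonuclease	VV,AABBDD,DD,HH,Bd
PP2C	Protein phosphatase 2C	VV,AABBDD,AA,DD,HH
Kelch_1	Kelch motif	VV,AABBDD,AA,DD,HH
RVT_1	Reverse transcriptase	VV,AA
rve	Integrase core domain	VV,AA
zf-RVT	Zinc-binding in reverse transcriptase	VV,AA
DUF948	Domain of unknown function	VV
NAM-associated	EF-hand domain pair	VV
PRT_C	NPR1/NIM1 like defence protein C terminal	VV
Jacalin	Jacalin-like lectin domain	AABBDD,DD,HH,Bd,Os
DUF761	Cotton fibre expressed protein	AABBDD,DD,Os
Exo70	Exo70 exocyst complex subunit	AABBDD,AA,HH
Motile_Sperm	MSP (major sperm protein) domain	AABBDD,AA,DD
CG-1	CG-1 domains	AABBDD,AA
DUF295	Unknown function	AABBDD,AA
Ank_2	Ankyrin repeats	AABBDD,AA
TB2_DP1_HVA22	TB2/DP1, HVA22 family	AABBDD,DD
DUF296	Plants and prokaryotes conserved (PCC) domain	AABBDD,DD
GRAS	GRAS (GAI, RGA, SCR) family	AABBDD,DD
Myb_DNA-binding	Myb-like DNA-binding domain	AABBDD,Bd
AP2	AP2 domain	AABBDD,Bd
RIP	Ribosome inactivating protein	AABBDD,HH
VQ	VQ motif	AABBDD,Os
AvrRpt-cleavage	Cleavage site for pathogenic type III effector avirulence factor Avr	DD,HH
BPS1	Staphylococcal nuclease homologue	AABBDD
CPSF100_C	Tudor domain	AABBDD
Ceramidase	Bacterial protein of unknown function	AABBDD
TIG	No apical meristem-associated C-terminal domain	AABBDD
zf-RING_2	Phosphoribosyltransferase C-terminal	AABBDD
Aldo_ket_red	AUX/IAA family	AA
BTB	FNIP Repeat	AA
CwfJ_C_1	Glutaredoxin	AA
CwfJ_C_2	Paired amphipathic helix repeat	AA
DUF3420	Zinc-finger of the FCS-type, C2-C2	AA
DUF3615	LSD1 zinc finger	AA
DUF4216	C1 domain	AA
DUF4218	F-box	AA
EF-hand_7	Transport inhibitor response 1 protein domain	AA
NPR1_like_C	Protein BYPASS1-related	AA
PARP	Cleavage and polyadenylation factor 2 C-terminal	AA
PTEN_C2	Ceramidase	AA
RST	IPT/TIG domain	AA
RVT_3	Ring finger domain	AA
Retrotran_gag_2	Aldo/keto reductase family	AA
XH	BTB/POZ domain	AA
gag_pre-integrs	Protein similar to CwfJ C-terminus 1	AA
tRNA_synt_2f	Protein similar to CwfJ C-terminus 2	AA
zf-CCHC_4	Domain of unknown function	AA
SNase	Protein of unknown function	DD
TUDOR	Domain of unknown function	DD
AUX_IAA	Poly (ADP-ribose) polymerase catalytic domain	HH
FNIP	C2 domain of PTEN tumour-suppressor protein	HH
Glutaredoxin	RCD1-SRO-TAF4 (RST) plant domain	HH
PAH	Reverse transcriptase-like	HH
zf-FLZ	Gag-polypeptide of LTR copia-type	HH
zf-LSD1	XH domain	HH
C1_2	GAG-pre-integrase domain	Os
F-box_5	Glycyl-tRNA synthetase beta subunit	Os
Transp_inhibit	Zinc knuckle	Os
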