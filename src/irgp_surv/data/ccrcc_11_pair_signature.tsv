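gene_a	gene_b	immune_process_a	immune_process_b	coefficient
PSMD11	NFKB1	Antigen_Processing_and_Presentation	Antimicrobials/BCRSignalingPathway/TCRsignalingPathway	0.0114928716374979
PSMD11	F2RL1	Antigen_Processing_and_Presentation	Antimicrobials	0.150699162881823
SLC10A2	AGER	Antigen_Processing_and_Presentation	Antimicrobials	-0.0350143079368729
CXCL2	GMFB	Antimicrobials/Chemokines/Cytokines	Cytokines	0.010646975575061
IL6	TGFB2	Antimicrobials/Chemokines/Cytokines	Cytokines/TGFb_Family_Member	0.0131725045908718
TLR7	IL20RB	Antimicrobials	Cytokine_Receptors/Interleukins_Receptor	-0.132192547462545
TYK2	KL	Antimicrobials	Cytokines	0.0225301659700258
IRF9	AR	Antimicrobials	Cytokine_Receptors	0.123358847050174
BIRC5	AR	Antimicrobials	Cytokine_Receptors	0.0167267736278587
PTK2	PLCG1	Antimicrobials	NaturalKiller_Cell_Cytotoxicity/TCRsignalingPathway	-0.0485464799522758
PLAUR	TEK	Chemokine_Receptors/Cytokine_Receptors	Cytokine_Receptors	0.154162736753599
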