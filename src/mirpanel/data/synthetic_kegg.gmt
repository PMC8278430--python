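SYN_CHOLINERGIC	synthetic stand-in: cholinergic synapse	GNB1	GNG12	CAMK2A	KCNQ2	CHRM1
SYN_DOPAMINERGIC	synthetic stand-in: dopaminergic synapse	GNAL	GNB1	GNG12	CAMK2A	GSK3B
SYN_GABAERGIC	synthetic stand-in: GABAergic synapse	GABRG2	GAD1	GABARAPL1	SLC6A1	GNB1
SYN_GLUTAMATERGIC	synthetic stand-in: glutamatergic synapse	GRIN2B	SLC1A2	SLC1A1	GNB1	MAPK1	GNAQ
AXON_GUIDANCE	synthetic stand-in: axon guidance	ROBO2	DCC	EFNA3	GSK3B	MAPK1
NEUROACTIVE_LR	synthetic stand-in: neuroactive ligand-receptor interaction	GRIN2B	GABRG2	CHRM1	NTRK2
MAPK_SIGNALING	synthetic stand-in: MAPK signaling pathway	MAPK1	MAP2K1	AKT1	EGFR	TP53	NTRK2
CALCIUM_SIGNALING	synthetic stand-in: calcium signaling pathway	CAMK2A	GNAQ	EGFR	CHRM1
ALZHEIMERS	synthetic stand-in: Alzheimer disease	APP	PSEN1	BACE1	GSK3B	GRIN2B
CANCER_PATHWAYS	synthetic stand-in: pathways in cancer	TP53	MYC	CCND1	AKT1	EGFR	PIK3R1	WNT1
INSULIN_SIGNALING	synthetic stand-in: insulin signaling pathway	INSR	AKT1	PIK3R1	HK2
WNT_SIGNALING	synthetic stand-in: Wnt signaling pathway	WNT1	GSK3B	CCND1	TP53
LTP	synthetic stand-in: long-term potentiation	GRIN2B	CAMK2A	MAPK1	GNAQ
GAP_JUNCTION	synthetic stand-in: gap junction	GNAQ	EGFR	MAPK1	GNAI1
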