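mirna	gene
miR-424-5p	GNAQ
miR-424-5p	GNB1
miR-424-5p	GRIN2B
miR-424-5p	SLC1A2
miR-424-5p	MAP2K1
miR-424-5p	CCND1
miR-424-5p	WNT1
miR-424-5p	PIK3R1
miR-424-5p	ROBO2
miR-424-5p	EFNA3
miR-500a-5p	GNAL
miR-500a-5p	GNG12
miR-500a-5p	GABRG2
miR-500a-5p	SLC1A1
miR-500a-5p	GAD1
miR-500a-5p	DCC
miR-500a-5p	NTRK2
miR-500a-5p	MAPK1
miR-500a-5p	CAMK2A
miR-500a-5p	GNB1
miR-500a-5p	GABARAPL1
miR-664a-3p	TP53
miR-664a-3p	MYC
miR-664a-3p	AKT1
miR-664a-3p	EGFR
miR-664a-3p	CCND1
miR-664a-3p	INSR
miR-664a-3p	PPARG
miR-664a-3p	HK2
miR-197-5p	APP
miR-197-5p	PSEN1
miR-197-5p	TFCP2
miR-197-5p	BACE1
miR-197-5p	GSK3B
miR-197-5p	MAPK1
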