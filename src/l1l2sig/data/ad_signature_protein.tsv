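probeset_id	gene_symbol	entrez_id	frequency
EGF_1	EGF	1950	100
PDGF-BB_1	PDGFB	5155	100
RANTES_1	CCL5	6352	100
TNFa	TNF	7124	100
GCSF_1	CSF3	1440	100
ICAM-1_1	ICAM1	3383	100
IL-1a	IL1A	3552	90
M-CSF_1	CSF1	1435	90
PARC_1	CCL18	6362	80
Acrp30_1	ADIPOQ	9370	70
ANG-2_1	ANGPT2	285	70
IL-8_1	IL8	3576	60
IL-3_1	IL3	3562	60
IL-11_1	IL11	3589	60
IL-6 R_1	IL6R	3570	50
IGFBP-6_1	IGFBP6	3489	50
MSP-a_1	MST1	4485	50
TRAIL R3_1	TNFRSF10C	8794	40
ANG_1	ANGTP1	284	40
AgRP(ART)_1	AGRP	181	40
TRAIL R4_1	TNFRSF10D	8793	40
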