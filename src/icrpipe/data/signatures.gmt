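BINDEA_T_CELLS	immune cell metagene	CD2	CD3D	CD3E	CD3G	CD6	TRAT1	CD28	LCK	ITM2A
BINDEA_T_HELPER_CELLS	immune cell metagene	CD4	ANP32B	ASF1A	BATF	ICOS
BINDEA_CD8_T_CELLS	immune cell metagene	CD8A	CD8B	GZMM	FLT3LG	PRF1
BINDEA_CYTOTOXIC_CELLS	immune cell metagene	GZMA	GZMB	GZMH	GNLY	PRF1	KLRB1	KLRD1	KLRK1	NKG7	CTSW
BINDEA_TH1_CELLS	immune cell metagene	IFNG	TBX21	IL12RB2	STAT4	CD38	LTA
BINDEA_TH2_CELLS	immune cell metagene	GATA3	IL26	LAIR2	SMAD2	PMCH	CXCR6
BINDEA_TH17_CELLS	immune cell metagene	IL17A	IL17RA	RORC	CCR6
BINDEA_TFH_CELLS	immune cell metagene	CXCL13	ICOS	PDCD1	CD200	BCL6
BINDEA_TREG_CELLS	immune cell metagene	FOXP3	IL2RA	IKZF2	TGFB1
BINDEA_TCM_CELLS	immune cell metagene	ATM	CASP8	CDC14A	NEFL
BINDEA_TEM_CELLS	immune cell metagene	EOMES	CCR2	EWSR1	LTK
BINDEA_TGD_CELLS	immune cell metagene	CD160	FEZ1	TRGC2
BINDEA_NK_CELLS	immune cell metagene	NCR1	KLRF1	KIR2DL3	XCL1	XCL2
BINDEA_NK_CD56DIM_CELLS	immune cell metagene	KIR2DL1	KIR2DS1	KIR3DL1	IL21R	SPON2
BINDEA_NK_CD56BRIGHT_CELLS	immune cell metagene	NCAM1	FOXJ1	PLA2G6	XCL1
BINDEA_B_CELLS	immune cell metagene	CD19	MS4A1	CD79A	CD79B	BLK	TNFRSF17
BINDEA_ADC	immune cell metagene	LAMP3	CCL22	CD83	CCR7	OAS3
BINDEA_DC	immune cell metagene	CCL13	CD209	HSD11B1	NPR1
BINDEA_IDC	immune cell metagene	CD1A	CD1B	CD1E	F13A1	SYT17
BINDEA_PDC	immune cell metagene	IL3RA	CLEC4C	LILRA4
BINDEA_MACROPHAGES	immune cell metagene	CD68	CD163	MSR1	MRC1	SIGLEC1
BINDEA_MAST_CELLS	immune cell metagene	TPSAB1	TPSB2	CPA3	MS4A2	KIT
BINDEA_NEUTROPHILS	immune cell metagene	FCGR3B	CSF3R	FPR1	S100A12
BINDEA_EOSINOPHILS	immune cell metagene	IL5RA	CCR3	PRG2	EPX
IFN_ALPHA_ACTIVATION	pathway activation score	MX1	MX2	OAS1	OAS2	IFI27	IFI44	IFIT1	IFIT3	ISG15	IRF7
IFN_GAMMA_ACTIVATION	pathway activation score	STAT1	IRF1	GBP1	GBP2	CXCL9	CXCL10	CXCL11	HLA-DRA	IDO1	SOCS1
TNF_ALPHA_ACTIVATION	pathway activation score	TNF	NFKB1	NFKBIA	TNFAIP3	CCL2	IL6	IL1B	CXCL8
TP53_ACTIVATION	pathway activation score	CDKN1A	MDM2	BAX	GADD45A	RRM2B	SESN1	TP53I3	ZMAT3
APM_SCORE	antigen processing and presentation machinery	TAP1	TAP2	TAPBP	B2M	HLA-A	HLA-B	HLA-C	PSMB8	PSMB9	CALR
TIS	T cell-inflamed signature (18 genes)	CCL5	CD27	CD274	CD276	CD8A	CMKLR1	CXCL9	CXCR6	HLA-DQA1	HLA-DRB1	HLA-E	IDO1	LAG3	NKG7	PDCD1LG2	PSMB10	STAT1	TIGIT
TLS	tertiary lymphoid structure 12-chemokine signature	CCL2	CCL3	CCL4	CCL5	CCL8	CCL18	CCL19	CCL21	CXCL9	CXCL10	CXCL11	CXCL13
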