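drp1_deg_genes	synthetic stand-in for the Drp1-overexpression DEG list; intersection with survival_genes reproduces the published 12-gene signature	SLC4A7	PDCD2L	UPP1	ARL4C	NELL2	LEF1	SGK1	PDE4D	S1PR3	MCTP2	HES6	OLR1	ATF4	DDIT3	HSPD1	HSPA9	SOD2	TFAM	PPARGC1A	NRF1	NDUFA4	SDHB	UQCRC1	COX5A	ATP5F1A	VDAC1	SLC25A3	TIMM23	CHCHD4	YME1L1	SPG7	HTRA2	PMAIP1	BNIP3	BNIP3L	FUNDC1	PGAM5	MTFR1	MTFR2	DNM2	EIF2AK3	XBP1
drp1_ppi_genes	synthetic stand-in for the STRING first-shell DNM1L interactor list; intersection with survival_genes reproduces the published 7-gene signature	AFG3L2	BCL2	ITPR3	LONP1	OPTN	PHB	TOMM40	MFF	FIS1	MIEF1	MIEF2	MFN1	MFN2	OPA1	INF2	GDAP1	MTFP1	PINK1	PRKN	MUL1	MARCHF5	SYNJ2BP	RHOT1	RHOT2	VDAC2	TOMM20	TOMM22	SAMM50	IMMT	CHCHD3	DNAJA3	CLUH
survival_genes	synthetic stand-in for the sepsis-survival gene list; contains all 19 signature genes plus immune-response background genes	SLC4A7	PDCD2L	UPP1	ARL4C	NELL2	LEF1	SGK1	PDE4D	S1PR3	MCTP2	HES6	OLR1	AFG3L2	BCL2	ITPR3	LONP1	OPTN	PHB	TOMM40	CD3E	CD4	CD8A	IL7R	CCR7	GZMB	PRF1	HLA-DRA	CD74	LCK	ZAP70	ITK	IL10	IL6	TNF	CXCL8	CCL2	S100A8	S100A9	MMP8	MMP9	OLFM4	CEACAM8	ELANE	MPO	DEFA4	LCN2	ARG1	HP	CD177	FCGR1A	C3AR1	C5AR1	PLAUR	THBD	PROC	SERPINE1	F3	TLR2	TLR5	NLRP3	CASP1	GATA3	TBX21	FOXP3	CTLA4	PDCD1	LAG3	HAVCR2	BTLA
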