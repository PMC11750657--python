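deg_gs	12-gene DEG-based Drp1 signature	SLC4A7	PDCD2L	UPP1	ARL4C	NELL2	LEF1	SGK1	PDE4D	S1PR3	MCTP2	HES6	OLR1
ppi_gs	7-gene PPI-based Drp1 signature	AFG3L2	BCL2	ITPR3	LONP1	OPTN	PHB	TOMM40
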