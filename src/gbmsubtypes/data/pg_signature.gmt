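PG_poor_invasive	published 40-gene poor-prognosis (invasive) GBM program	MSN	SERPINB6	DYNLT3	DRG2	LGALS8	CBR1	S100A10	GPRASP1	LGALS3	PDPN	LRRFIP1	SDF4	DCTD	FRMD4B	TMBIM1	GSN	EMP3	ABCA1	LITAF	WDR1	TFRC	DNAJC10	CYB561	LOXL1	EFEMP2	DNTTIP2	F3	ANXA1	TP73-AS1	KHNYN	SLC12A7	ARL4C	NOL3	TMF1	PLOD2	CPQ	OSBPL9	DIRAS3	TRIP4	S100A11
PG_favorable_mitotic	published 40-gene favorable-prognosis (mitotic) GBM program	DHRS2	LUZP2	LBP	SMAD9	HPR	AKAP3	TMEM100	IGFBP1	H2AFY2	RFXAP	TRIM48	POU1F1	P2RY14	AKAP6	SEC61A2	CDHR1	DACH1	REST	MSTN	TAT	HIST1H4B	DDX6	CDH9	SSX3	NDUFA13	ZP2	GFRA1	F5	DLL3	SGCG	HSF2BP	SLC35E2	ALDH1A2	TP53TG5	CPB1	PDZD7	THNSL1	LIN28A	IL5	AMELY
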