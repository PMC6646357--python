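entrez	symbol	direction
4478	MSN	poor
5269	SERPINB6	poor
6990	DYNLT3	poor
1819	DRG2	poor
3964	LGALS8	poor
873	CBR1	poor
6281	S100A10	poor
9737	GPRASP1	poor
3958	LGALS3	poor
10630	PDPN	poor
9208	LRRFIP1	poor
51150	SDF4	poor
1635	DCTD	poor
23150	FRMD4B	poor
4114	TMBIM1	poor
2934	GSN	poor
2014	EMP3	poor
19	ABCA1	poor
9516	LITAF	poor
9948	WDR1	poor
7037	TFRC	poor
54431	DNAJC10	poor
1534	CYB561	poor
4016	LOXL1	poor
30008	EFEMP2	poor
30836	DNTTIP2	poor
2152	F3	poor
301	ANXA1	poor
57212	TP73-AS1	poor
23351	KHNYN	poor
10723	SLC12A7	poor
10123	ARL4C	poor
8996	NOL3	poor
7110	TMF1	poor
5352	PLOD2	poor
10404	CPQ	poor
114883	OSBPL9	poor
9077	DIRAS3	poor
9325	TRIP4	poor
6282	S100A11	poor
10202	DHRS2	favorable
338645	LUZP2	favorable
3929	LBP	favorable
4093	SMAD9	favorable
3250	HPR	favorable
10566	AKAP3	favorable
55273	TMEM100	favorable
3484	IGFBP1	favorable
55506	H2AFY2	favorable
5994	RFXAP	favorable
79097	TRIM48	favorable
5449	POU1F1	favorable
9934	P2RY14	favorable
9472	AKAP6	favorable
55176	SEC61A2	favorable
92211	CDHR1	favorable
1602	DACH1	favorable
5978	REST	favorable
2660	MSTN	favorable
6898	TAT	favorable
8366	HIST1H4B	favorable
1656	DDX6	favorable
1007	CDH9	favorable
10214	SSX3	favorable
51079	NDUFA13	favorable
7783	ZP2	favorable
2674	GFRA1	favorable
2153	F5	favorable
10683	DLL3	favorable
6445	SGCG	favorable
11077	HSF2BP	favorable
9906	SLC35E2	favorable
8854	ALDH1A2	favorable
27296	TP53TG5	favorable
1360	CPB1	favorable
79955	PDZD7	favorable
79896	THNSL1	favorable
79727	LIN28A	favorable
3567	IL5	favorable
266	AMELY	favorable
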