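KEGG_CELL_CYCLE	curated cell-cycle gene set (human symbols)	CDK1	CDK2	CDK4	CDK6	CDK7	CCNA1	CCNA2	CCNB1	CCNB2	CCNB3	CCND1	CCND2	CCND3	CCNE1	CCNE2	CCNH	CDC6	CDC7	CDC14A	CDC14B	CDC20	CDC23	CDC25A	CDC25B	CDC25C	CDC26	CDC27	CDC45	CDKN1A	CDKN1B	CDKN1C	CDKN2A	CDKN2B	CDKN2C	CDKN2D	CHEK1	CHEK2	E2F1	E2F2	E2F3	E2F4	E2F5	MCM2	MCM3	MCM4	MCM5	MCM6	MCM7	ORC1	ORC2	ORC3	ORC4	ORC5	ORC6	RB1	RBL1	RBL2	TP53	WEE1	WEE2	PLK1	BUB1	BUB1B	BUB3	MAD1L1	MAD2L1	MAD2L2	TTK	PCNA	PTTG1	PTTG2	ESPL1	SMC1A	SMC1B	SMC3	RAD21	STAG1	STAG2	SKP1	SKP2	CUL1	RBX1	FZR1	ANAPC1	ANAPC2	ANAPC4	ANAPC5	ANAPC7	ANAPC10	ANAPC11	ANAPC13	CDC16	GADD45A	GADD45B	GADD45G	ATM	ATR	MDM2	ABL1	HDAC1	HDAC2	TFDP1	TFDP2	TGFB1	TGFB2	TGFB3	SMAD2	SMAD3	SMAD4	MYC	ZBTB17	GSK3B	DBF4	PKMYT1	YWHAB	YWHAE	YWHAG	YWHAH	YWHAQ	YWHAZ	SFN	EP300	CREBBP
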