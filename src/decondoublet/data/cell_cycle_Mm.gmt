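KEGG_CELL_CYCLE	curated cell-cycle gene set (mouse symbols)	Cdk1	Cdk2	Cdk4	Cdk6	Cdk7	Ccna1	Ccna2	Ccnb1	Ccnb2	Ccnb3	Ccnd1	Ccnd2	Ccnd3	Ccne1	Ccne2	Ccnh	Cdc6	Cdc7	Cdc14a	Cdc14b	Cdc20	Cdc23	Cdc25a	Cdc25b	Cdc25c	Cdc26	Cdc27	Cdc45	Cdkn1a	Cdkn1b	Cdkn1c	Cdkn2a	Cdkn2b	Cdkn2c	Cdkn2d	Chek1	Chek2	E2f1	E2f2	E2f3	E2f4	E2f5	Mcm2	Mcm3	Mcm4	Mcm5	Mcm6	Mcm7	Orc1	Orc2	Orc3	Orc4	Orc5	Orc6	Rb1	Rbl1	Rbl2	Tp53	Wee1	Wee2	Plk1	Bub1	Bub1b	Bub3	Mad1l1	Mad2l1	Mad2l2	Ttk	Pcna	Pttg1	Pttg2	Espl1	Smc1a	Smc1b	Smc3	Rad21	Stag1	Stag2	Skp1	Skp2	Cul1	Rbx1	Fzr1	Anapc1	Anapc2	Anapc4	Anapc5	Anapc7	Anapc10	Anapc11	Anapc13	Cdc16	Gadd45a	Gadd45b	Gadd45g	Atm	Atr	Mdm2	Abl1	Hdac1	Hdac2	Tfdp1	Tfdp2	Tgfb1	Tgfb2	Tgfb3	Smad2	Smad3	Smad4	Myc	Zbtb17	Gsk3b	Dbf4	Pkmyt1	Ywhab	Ywhae	Ywhag	Ywhah	Ywhaq	Ywhaz	Sfn	Ep300	Crebbp
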