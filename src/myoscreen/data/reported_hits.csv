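gene,human_ortholog,direction,tier
Atg1,ULK1/ULK2,positive,multi
Atg18,WIPI1/WIPI2,positive,multi
Atg2,ATG2A/ATG2B,positive,multi
Atg6,BECN1,positive,multi
Atg9,ATG9A/B,positive,multi
Aut1,ATG3,positive,multi
CG10253,AGPS,positive,multi
CG12360,TRABD,positive,multi
CG1347,RB1CC1,positive,multi
CG31033,ATG16L1,positive,multi
CG31935,RAB3GAP1,positive,multi
CG32226,TECPR1,positive,multi
CG41099,ANKFY1,positive,multi
CG6199,PLOD3,positive,multi
CG7053,ATG101,positive,multi
CG7112,RABGAP1/1L,positive,multi
CG8678,WIPI1/WIPI2,positive,multi
Chc,CLTC,positive,multi
Cul-2,CUL2,positive,multi
garz,GBF1,positive,multi
Hel25E,DDX39B,positive,multi
Khc,KIF5B,positive,multi
Mcm2,MCM2,positive,multi
Pi3K59F,PIK3C3,positive,multi
Pros26.4,PSMC1,positive,multi
Rab3-GAP,RAB3GAP2,positive,multi
Rpn1,PSMD2,positive,multi
Rpt1,PSMC2,positive,multi
sgg,GSK3B,positive,multi
shi,DNM2,positive,multi
Tao-1,TAOK1,positive,multi
ade2,PFAS,negative,multi
Cctgamma,CCT3,negative,multi
Cdc37,CDC37,negative,multi
CG42233,WDR22,negative,multi
CG9485,AGL,negative,multi
Gp93,HSP90B1,negative,multi
Nek2,NEK7,negative,multi
Nipsnap,GBAS/NIPSNAP1,negative,multi
pk,PRICKLE2,negative,multi
Pk92B,MAP3K6/MAP3K15/MAP3K5,negative,multi
Pros45,PSMC5,negative,multi
Rpt3R,PSMC4,negative,multi
Atg12,ATG12,positive,single
Atg13,ATG13,positive,single
Atg5,ATG5,positive,single
Atg7,ATG7,positive,single
CG13745,FANCI,positive,single
CG6904,GYS1,positive,single
gish,CSNK1G3,positive,single
Mhc,MYH2,positive,single
Nup154,NUP155,positive,single
pic,DDB1,positive,single
Rab1,RAB1A,positive,single
Sas,NANS,positive,single
Sec61alpha,SEC61A2,positive,single
slim,KIAA0265,positive,single
Usp7,USP7,positive,single
Vps16A,PTPRA,positive,single
aPKC,PRKCI,negative,single
CG3590,ADSL,negative,single
CG9784,INPP5K,negative,single
Gfat1,GFPT1,negative,single
Mpk2,MAPK14,negative,single
Nat1,NARG1,negative,single
Nedd4,NEDD4,negative,single
Nsf2,NSF,negative,single
Pfk,PFKL/PFKP,negative,single
Rpt6R,PSMC5,negative,single
Stlk,LYK5,negative,single
Tcp-1eta,CCT7,negative,single
Tudor-SN,SND1,negative,single
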