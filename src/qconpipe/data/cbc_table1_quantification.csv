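protein,peptide,mean_amol_per_cell,sd_amol_per_cell,n,median_amol_per_cell,pct_total_protein,dpop_rank,dpop_score
rbcL,DTDILAAFR,37.7,6.6,24,36.2,6.88,1,1.0
rbcL,LTYYTPDYVVR,35.9,5.6,24,,,2,0.73
rbcL,FLFVAEAIYK,37.5,4.6,24,,,3,0.68
RBCS,AFPDAYVR,29.0,7.2,11,24.6,1.45,1,1.0
RBCS,AYVSNESAIR,22.2,3.1,24,,,2,1.0
RBCS,LVAFDNQK,29.3,4.6,19,,,3,0.82
PGK1,ADLNVPLDK,1.6,0.4,24,2.0,0.31,3,0.83
PGK1,LSELLGKPVTK,2.1,0.4,23,,,25,0.24
PGK1,TFNDALADAK,2.4,0.4,24,,,11,0.65
GAP3,AVSLVLPSLK,6.8,1.5,24,6.6,0.91,10,0.45
GAP3,VLITAPAK,6.9,1.1,12,,,1,1.0
TPI1,LVDELNAGTIPR,0.3,0.1,23,0.3,0.03,1,1.0
TPI1,SLFGESNEVVAK,0.4,0.2,20,,,3,0.47
FBA3,ALQNTVLK,11.5,2.5,24,10.1,1.4,4,0.50
FBA3,SVVSIPHGPSIIAAR,8.8,1.5,24,,,1,1.0
FBP1,IYSFNEGNYGLWDDSVK,1.9,1.3,24,0.5,0.08,12,0.26
FBP1,TLLYGGIYGYPGDAK,0.5,0.1,23,,,7,0.48
FBP1,VPLFIGSK,0.2,0.04,12,,,1,1.0
SBP1,LLFEALK,1.3,0.3,12,1.2,0.15,2,1.0
SBP1,LTNITGR,1.1,0.3,11,,,9,0.52
TRK1,FLAIDAINK,3.2,0.8,23,2.0,0.53,2,0.90
TRK1,NPDFFNR,1.5,0.4,19,,,4,0.66
TRK1,VSTLIGYGSPNK,1.9,0.5,24,,,5,0.56
RPE1,FIESQVAK,0.4,0.1,8,0.4,0.04,3,0.80
RPE1,GVNPWIEVDGGVTPENAYK,1.2,0.4,21,,,5,0.66
RPE1,SDIIVSPSILSADFSR,0.2,0.4,22,,,1,1.0
RPI1,LANLPEVK,0.4,0.1,20,0.3,0.03,2,0.78
RPI1,LQNIVGVPTSIR,0.4,0.1,24,,,1,1.0
PRK1,GHSLESIK,3.9,1.4,18,1.8,0.25,11,0.26
PRK1,IYLDISDDIK,1.6,0.3,24,,,6,0.65
PRK1,VAELLDFK,1.5,0.2,12,,,1,1.0
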