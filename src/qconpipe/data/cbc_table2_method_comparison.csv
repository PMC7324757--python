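protein,rank_qconcat,rank_ibaq,amol_per_cell_qconcat,amol_per_cell_mass_western,um_chloroplast_empai,um_chloroplast_qconcat
rbcL,1,2,36.2,42.2,304.5,268.2
RBCS,2,6,24.6,1.0,,182.5
FBA3,3,9,10.1,4.2,658.5,75.1
GAP3,4,30,6.6,1.8,651.5,48.9
PGK1,5,49,2.0,0.26,477.2,14.9
TRK1,6,43,2.0,1.43,232.2,14.8
PRK1,7,66,1.8,1.67,451.3,13.1
SBP1,8,138,1.2,0.09,149.6,8.7
FBP1,9,185,0.55,0.23,121.0,4.1
RPE1,10,394,0.45,0.2,87.7,3.3
RPI1,11,294,0.34,0.35,68.1,2.5
TPI1,12,276,0.28,0.16,44.3,2.1
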