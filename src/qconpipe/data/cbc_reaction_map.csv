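enzyme,number,subunits,reversible,metabolite,role
Rubisco,1,rbcL,False,RuBP,substrate
PGK1,2,PGK1,False,3PGA,substrate
GAP3,3,GAP3,False,BPGA,substrate
TPI1,4,TPI1,True,GAP,substrate
TPI1,4,TPI1,True,DHAP,product
FBA3,5,FBA3,True,GAP,substrate
FBA3,5,FBA3,True,DHAP,substrate
FBA3,5,FBA3,True,E4P,substrate
FBA3,5,FBA3,True,FBP,product
FBA3,5,FBA3,True,SBP,product
FBP1,6,FBP1,False,FBP,substrate
SBP1,7,SBP1,False,SBP,substrate
TRK1,8,TRK1,True,F6P,substrate
TRK1,8,TRK1,True,GAP,substrate
TRK1,8,TRK1,True,S7P,substrate
TRK1,8,TRK1,True,X5P,product
TRK1,8,TRK1,True,E4P,product
TRK1,8,TRK1,True,R5P,product
RPE1,9,RPE1,True,X5P,substrate
RPE1,9,RPE1,True,Ru5P,product
RPI1,10,RPI1,True,R5P,substrate
RPI1,10,RPI1,True,Ru5P,product
PRK1,11,PRK1,False,Ru5P,substrate
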