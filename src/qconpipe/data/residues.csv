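residue,name,monoisotopic_da,average_da,n_nitrogen,chromophore
A,alanine,71.03711,71.0779,1,
C,cysteine,103.00919,103.1429,1,C
D,aspartate,115.02694,115.0874,1,
E,glutamate,129.04259,129.1140,1,
F,phenylalanine,147.06841,147.1739,1,
G,glycine,57.02146,57.0513,1,
H,histidine,137.05891,137.1393,3,
I,isoleucine,113.08406,113.1576,1,
K,lysine,128.09496,128.1723,2,
L,leucine,113.08406,113.1576,1,
M,methionine,131.04049,131.1961,1,
N,asparagine,114.04293,114.1026,2,
P,proline,97.05276,97.1152,1,
Q,glutamine,128.05858,128.1292,2,
R,arginine,156.10111,156.1857,4,
S,serine,87.03203,87.0773,1,
T,threonine,101.04768,101.1039,1,
V,valine,99.06841,99.1311,1,
W,tryptophan,186.07931,186.2099,2,W
Y,tyrosine,163.06333,163.1733,1,Y
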