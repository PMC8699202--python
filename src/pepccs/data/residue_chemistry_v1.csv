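symbol,one_hot_index,H,C,N,O,S,acidic,modified,amide,nonpolar,small,uncharged_polar,aliphatic_nonpolar,aromatic,positive,hydroxyl,dyad_ND,dyad_EQ,hydropathy,bulkiness,polarity,volume,isoelectric_point,helix_propensity,mono_mass
A,0,5,3,1,1,0,0,0,0,1,1,0,1,0,0,0,0,0,6.3,11.5,8.1,88.6,6.0,1.42,71.037114
C,1,5,3,1,1,1,0,0,0,0,0,1,0,0,0,0,0,0,7.0,13.46,5.5,108.5,5.07,0.7,103.009185
D,2,5,4,1,3,0,1,0,0,0,0,0,0,0,0,0,1,0,1.0,11.68,13.0,111.1,2.77,1.01,115.026943
E,3,7,5,1,3,0,1,0,0,0,0,0,0,0,0,0,0,1,1.0,13.57,12.3,138.4,3.22,1.51,129.042593
F,4,9,9,1,1,0,0,0,0,1,0,0,0,1,0,0,0,0,7.3,19.8,5.2,189.9,5.48,1.13,147.068414
G,5,3,2,1,1,0,0,0,0,1,1,0,1,0,0,0,0,0,4.1,3.4,9.0,60.1,5.97,0.57,57.021464
H,6,7,6,3,1,0,0,0,0,0,0,0,0,0,1,0,0,0,1.3,13.69,10.4,153.2,7.59,1.0,137.058912
I,7,11,6,1,1,0,0,0,0,1,0,0,1,0,0,0,0,0,9.0,21.4,5.2,166.7,6.02,1.08,113.084064
K,8,12,6,2,1,0,0,0,0,0,0,0,0,0,1,0,0,0,0.6,15.71,11.3,168.6,9.74,1.16,128.094963
L,9,11,6,1,1,0,0,0,0,1,0,0,1,0,0,0,0,0,8.3,21.4,4.9,166.7,5.98,1.21,113.084064
M,10,9,5,1,1,1,0,0,0,1,0,0,0,0,0,0,0,0,6.4,16.25,5.7,162.9,5.74,1.45,131.040485
N,11,6,4,2,2,0,0,0,1,0,0,1,0,0,0,0,1,0,1.0,12.82,11.6,114.1,5.41,0.67,114.042927
P,12,7,5,1,1,0,0,0,0,1,1,0,0,0,0,0,0,0,2.9,17.43,8.0,112.7,6.3,0.57,97.052764
Q,13,8,5,2,2,0,0,0,1,0,0,1,0,0,0,0,0,1,1.0,14.45,10.5,143.8,5.65,1.11,128.058578
R,14,12,6,4,1,0,0,0,0,0,0,0,0,0,1,0,0,0,0.0,14.28,10.5,173.4,10.76,0.98,156.101111
S,15,5,3,1,2,0,0,0,0,0,1,1,0,0,0,1,0,0,3.7,9.47,9.2,89.0,5.68,0.77,87.032028
T,16,7,4,1,2,0,0,0,0,0,0,1,0,0,0,1,0,0,3.8,15.77,8.6,116.1,5.6,0.83,101.047678
V,17,9,5,1,1,0,0,0,0,1,0,0,1,0,0,0,0,0,8.7,21.57,5.9,140.0,5.96,1.06,99.068414
W,18,10,11,2,1,0,0,0,0,1,0,0,0,1,0,0,0,0,3.6,21.67,5.4,227.8,5.89,1.08,186.079313
Y,19,9,9,1,2,0,0,0,0,0,0,1,0,1,0,1,0,0,3.2,18.03,6.2,193.6,5.66,0.69,163.063329
m,20,9,5,1,2,1,0,1,0,0,0,1,0,0,0,0,0,0,6.4,16.25,5.7,162.9,5.74,1.45,147.0354
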