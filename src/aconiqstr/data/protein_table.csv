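# Cardiotoxicity-associated proteins and their literature report frequencies,
# the seed list of the protein-protein interaction network.
name,classification,frequency
RYR2,Ryanodine receptor 2,19
RYR1,Ryanodine receptor 1,15
GJA1,Gap junction alpha-1 protein (connexin43),13
SLC8A1,Sodium/calcium exchanger 1,11
ATP2A1,Calcium transporting ATPase fast twitch 1,9
KCNH2,Potassium voltage-gated channel H2,7
SCN3A,Sodium voltage-gated channel type 3,3
SCN2A,Sodium voltage-gated channel type 2,3
SCN8A,Sodium voltage-gated channel type 8,2
SCN1A,Sodium voltage-gated channel type 1,2
SCN4A,Sodium voltage-gated channel type 4,1
KCNJ3,Potassium inwardly-rectifying channel J3,1
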