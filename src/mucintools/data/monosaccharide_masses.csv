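letter,name,formula,monoisotopic_mass_da
N,HexNAc,C8H13NO5,203.079373
H,Hex,C6H10O5,162.052823
A,NeuAc,C11H17NO8,291.095417
F,dHex,C6H10O4,146.057909
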