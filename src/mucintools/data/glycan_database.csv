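composition,monoisotopic_mass_da,core_category
N1,203.079373,Tn
N1A1,494.174789,Tn
N1F1,349.137281,Tn
N1H1,365.132196,core1
N1H1F1,511.190105,core1
N1H1A1,656.227612,core1
N1H1A2,947.323029,core1
N2,406.158745,other
N2H1,568.211568,core2
N2H2,730.264392,core2
N2H2A1,1021.359808,core2
N2H2A2,1312.455225,core2
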