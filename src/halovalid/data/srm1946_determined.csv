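analyte,determined_mean,determined_expanded_u,n
Hexachlorobenzene,6.47,1.5,3
alpha-HCH,5.44,1.4,3
Lindane,0.89,0.26,3
BDE-28,0.467,0.067,3
BDE-47,30.2,5.1,3
BDE-99,22.0,3.7,3
BDE-100,9.04,1.8,3
BDE-153,3.16,0.69,3
BDE-154,6.57,1.2,3
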