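analyte,u_r_repro_pct,b_r_pct,u_r_cm_pct,u_r_ref_pct
"Hexachloro-1,3-butadiene",8.01,-4.66,0.909,1.15
Pentachlorobenzene,9.90,-5.15,0.676,0.250
alpha-HCH,7.83,-10.6,0.154,0.475
Hexachlorobenzene,8.42,7.38,0.274,1.00
beta-HCH,8.13,-11.6,0.954,0.150
Lindane,6.04,-13.0,0.451,0.866
delta-HCH,7.15,-9.40,1.34,0.330
Heptachlor,7.60,-6.23,2.74,0.250
BDE-28,6.48,-1.28,2.78,0.295
BDE-47,7.98,1.90,1.56,0.300
BDE-100,9.75,0.192,0.913,0.300
BDE-99,8.01,-0.879,2.06,0.300
BDE-154,8.50,1.17,2.89,0.300
BDE-153,9.00,5.08,3.50,0.300
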