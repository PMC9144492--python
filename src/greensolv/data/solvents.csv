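name,cas,molar_mass_g_mol,available,htping,htpinh,ttp,atp,gwp,odp,pcop,ar
water,7732-18-5,18.02,True,,,,,,,,
methanol,67-56-1,32.04,True,,,,,,,,
DMSO,67-68-5,78.13,True,0.130,0.00,0.13,0.0000620,0.0,0.0,11.40,0.0
DMF,68-12-2,73.09,True,0.675,0.81,0.68,0.000200,0.0,0.0,0.00,0.0
4FM,4394-85-8,115.13,True,0.254,0.00,0.25,0.000999,0.0,0.0,0.00,0.0
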