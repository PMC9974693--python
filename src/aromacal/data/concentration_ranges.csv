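compound,conc_min,conc_max,unit
Acetaldehyde,3.2,40.1,mg/kg
Ethanol,102.6,431.0,mg/kg
Methyl acetate,18.6,1058.8,ug/kg
Isobutanal,7.4,293.9,ug/kg
1-Propanol,309.9,2117.3,ug/kg
Diacetyl,29.3,224.1,ug/kg
Ethyl acetate,92.7,12784.3,ug/kg
2-Butanol,43.9,318.9,ug/kg
Isobutanol,68.5,3000.2,ug/kg
3-Methylbutanal,1.9,35.7,ug/kg
Acetic acid,8.2,363.8,mg/kg
2-Methylbutanal,1.0,36.6,ug/kg
2-Ethylfuran,0.03,0.36,ug/kg
1-Butanol,11.0,182.0,ug/kg
1-Penten-3-one,1.5,17.7,ug/kg
2-Pentanone,2.4,3.88,ug/kg
1-Penten-3-ol,14.7,131.4,ug/kg
Pentanal,1.4,16.8,ug/kg
Ethyl propanoate,0.2,0.8,ug/kg
Propyl acetate,0.7,9.8,ug/kg
Ethyl isobutanoate,0.2,2.3,ug/kg
3-Methylbutanol,74.9,2816.8,ug/kg
2-Methylbutanol,26.0,883.5,ug/kg
Isobutyl acetate,0.7,16.3,ug/kg
1-Pentanol,1.7,5.2,ug/kg
Ethyl butanoate,0.3,1.0,ug/kg
Hexanal,2.0,10.8,mg/kg
Ethyl 3-methylbutanoate,0.1,1.1,ug/kg
3-Methylbutyl acetate,0.2,6.4,ug/kg
2-Methylbutyl acetate,0.3,1.4,ug/kg
2-Hexenal,793.1,5902.1,ug/kg
1-Hexanol,212.1,2025.7,ug/kg
2-Heptanone,50,50,ug/kg
2-Heptanol,253.1,526.5,ug/kg
Methyl hexanoate,0.1,0.4,ug/kg
"(E,E)-2,4-Hexadienal",23.3,214.0,ug/kg
beta-Myrcene,0.1,0.2,ug/kg
2-Pentylfuran,0.1,2.9,ug/kg
Ethyl hexanoate,0.1,3.3,ug/kg
Hexyl acetate,0.5,5.5,ug/kg
Linalool,3.5,38.9,ug/kg
Hexyl butanoate,0.1,2.1,ug/kg
Nerol,135.4,135.4,ug/kg
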