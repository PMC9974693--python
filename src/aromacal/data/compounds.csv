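name,taste_threshold_ug_L,threshold_source,attribute_override
Acetaldehyde,22,water,
Pentane,,"not quantified; literature gives > 500000 (fish note)",
Ethanol,10000,water,
Methyl acetate,50,in beer,
Isobutanal,0.4,water,
1-Propanol,7000,water,
Diacetyl,5.4,water,
Ethyl acetate,3000,water,
2-Butanol,5100,water,
Isobutanol,8000,water,
3-Methylbutanal,170,water,
Acetic acid,54000,water,
2-Methylbutanal,0.8,water,
2-Ethylfuran,,no threshold available,
1-Butanol,500,water,
1-Penten-3-one,1,water,
2-Pentanone,60000,water,
1-Penten-3-ol,3,water,
Pentanal,70,water,
Ethyl propanoate,4,water,
Propyl acetate,800,water,
"2,4,5-Trimethyl-1,3-dioxolan",,not quantified; no threshold available,
Ethyl isobutanoate,0.03,water,
3-Methylbutanol,100,water,
2-Methylbutanol,5500,water,
Isobutyl acetate,300,water,
1-Pentanol,4500,water,
Ethyl butanoate,0.13,water,
2-Penten-1-ol,,not quantified; no threshold available,
Hexanal,3.7,water,
Ethyl 3-methylbutanoate,0.01,water,
3-Methylbutyl acetate,3,water,
2-Methylbutyl acetate,1.2,in beer,
2-Hexenal,49,water,
1-Hexanol,200,water,green_vegetative
2-Heptanone,70,water; internal standard,
2-Heptanol,100,water,
Methyl hexanoate,75,in milk,
"(E,E)-2,4-Hexadienal",36,in oil,
beta-Myrcene,16.6,water,
2-Pentylfuran,4.8,water,
Ethyl hexanoate,0.5,water,
Hexyl acetate,40,water,
Octanal,0.52,not quantified,
Linalool,3.8,water,
Nonanal,4.25,not quantified,
Hexyl butanoate,,no threshold available,
2-Nonenal,0.5,not quantified,
Decanal,3,not quantified,
Nerol,,single detection; no threshold available,
Methyl geranate,,not quantified; no threshold available,
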