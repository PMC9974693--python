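compound,center_nm,width_nm,amplitude
Acetaldehyde,905,30,7.8125e-05
Ethanol,955,28,3.0359e-06
Methyl acetate,1010,32,5.1573e-03
Isobutanal,1065,30,1.2674e-02
Diacetyl,1120,34,1.9455e-02
1-Penten-3-one,1175,28,4.7619e-01
2-Methylbutanal,1230,32,1.0000e-01
1-Penten-3-ol,1285,30,2.3529e-02
Ethyl isobutanoate,1340,34,3.3333e+00
3-Methylbutanol,1395,30,1.9260e-03
Hexanal,1455,32,2.0000e-04
Ethyl 3-methylbutanoate,1510,28,1.0000e+01
2-Hexenal,1565,32,5.1546e-04
1-Hexanol,1620,30,1.2888e-03
Linalool,1668,26,4.3478e-01
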