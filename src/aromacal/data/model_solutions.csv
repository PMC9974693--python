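sample_id,compound,value,unit
A,Acetaldehyde,20000.0,ug/L
A,Ethanol,300000.0,ug/L
A,Methyl acetate,1000.0,ug/L
A,Isobutanal,40.0,ug/L
A,3-Methylbutanol,800.0,ug/L
A,Hexanal,4000.0,ug/L
A,Ethyl 3-methylbutanoate,1.0,ug/L
A,2-Hexenal,1000.0,ug/L
B,Acetaldehyde,30000.0,ug/L
B,Ethanol,400000.0,ug/L
B,Methyl acetate,900.0,ug/L
B,Isobutanal,50.0,ug/L
B,3-Methylbutanol,2000.0,ug/L
B,Hexanal,10000.0,ug/L
B,Ethyl 3-methylbutanoate,1.0,ug/L
B,2-Hexenal,6000.0,ug/L
C,Acetaldehyde,7000.0,ug/L
C,Ethanol,200000.0,ug/L
C,Methyl acetate,30.0,ug/L
C,Isobutanal,10.0,ug/L
C,3-Methylbutanol,90.0,ug/L
C,Hexanal,5000.0,ug/L
C,2-Hexenal,2000.0,ug/L
C,Linalool,40.0,ug/L
D,Acetaldehyde,40000.0,ug/L
D,Ethanol,400000.0,ug/L
D,Methyl acetate,150.0,ug/L
D,Isobutanal,250.0,ug/L
D,3-Methylbutanol,900.0,ug/L
D,Hexanal,7000.0,ug/L
D,2-Hexenal,2000.0,ug/L
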