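compound,average_ug_L,sd_ug_L,pc1,pc2,attribute,in_recalculated
Acetaldehyde,12800,8300,0.32460,0.25567,microbiological,1
Ethanol,329400,89600,0.18059,0.23393,microbiological,1
Methyl acetate,193.9,217.2,0.29181,-0.07682,fruity,1
Isobutanal,78.9,66.5,0.11353,0.47020,microbiological,1
Diacetyl,51.4,48.0,0.31879,0.24331,microbiological,0
1-Penten-3-one,2.1,3.1,0.19944,-0.41716,green_vegetative,0
2-Methylbutanal,10.0,8.6,0.16772,0.42861,microbiological,0
1-Penten-3-ol,42.5,22.6,0.29808,-0.22891,green_vegetative,0
Ethyl isobutanoate,0.3,0.6,0.34054,-0.07243,fruity,0
3-Methylbutanol,519.2,555.6,0.36021,0.00124,fruity,1
Hexanal,5000,1900,0.24045,-0.19385,green_vegetative,1
Ethyl 3-methylbutanoate,0.1,0.3,0.28938,-0.15741,fruity,1
2-Hexenal,1940.0,947.9,0.24562,-0.28788,green_vegetative,1
1-Hexanol,775.9,458.6,0.22333,0.08161,green_vegetative,0
Linalool,2.3,7.2,-0.09004,-0.16262,floral,1
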