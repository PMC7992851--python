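cas,name,exp_lc50,ecosar_lc50,ecosar_ad,test_lc50,test_ad,danish_lc50,danish_ad,vega_lc50,vega_ad,read_across_lc50,read_across_ad,trend_analysis_lc50,trend_analysis_ad,kate_lc50,kate_ad,note
120-82-1,"1,2,4-Trichlorobenzene",1.68,1.88,In,2.88,In,1.04,In,2.69,In,5.36,In,171,In,1.60,In,
81-15-2,Musk xylene,0.154,45.7,In,2.41,In,1.38,In,6.71,Out,6.90,In,0.55,In,NA,NA,typeset overlap: ECOSAR cell read as 45.7; stray AD token before KATE NA
75-09-2,Dichloromethane,27.01,46.0,In,59.06,In,NA,NA,81.92,In,148,In,115,In,51.00,In,fused cell: exp/ECOSAR read as 27.01/46.0
50-00-0,Formaldehyde,29.0,12.0,In,NA,NA,NA,NA,NA,NA,2610,In,8090,In,NA,NA,
77-47-4,Hexachlorocyclopentadiene,0.039,0.21,In,1.04,In,0.11,Out,0.07,Out,0.11,Out,NA,NA,NA,NA,
25637-99-4,Hexabromocyclododecane,0.0032,0.0035,Out,0.16,In,0.01,Out,0.43,Out,0.17,Out,-84.0,Out,0.00,Out,KATE stored as printed 0.00; negative trend value as printed
91-20-3,Naphthalene,1.96,5.94,In,8.14,In,3.26,Out,0.24,In,11.5,In,99.0,In,3.90,In,trend AD token garbled in source; read as In
1763-23-1,Heptadecafluorooctanesulfonic acid,37.04,16.9,In,NA,NA,18.20,Out,12.01,Out,63800,In,29900,In,NA,NA,
307-35-7,Perfluoro-1-octanesulfonyl fluoride,100,0.0051,Out,NA,NA,19.98,In,2.51,Out,NA,NA,NA,NA,NA,NA,
2795-39-3,Potassium perufluorooctane sulfonate,27.0,16.9,In,NA,NA,19.98,In,NA,NA,12000,In,17500,In,NA,NA,
25154-52-3,Nonylphenol,0.14,0.168,In,0.55,In,0.32,In,3.88,Out,3.58,In,0.57,In,0.12,In,
9016-45-9,NP-poly(ethyleneoxy)ethanol,0.15,0.211,Out,2.58,In,3.15,In,1.03,Out,12.70,Out,21.80,Out,0.09,Out,
67-66-3,Chloroform,29.0,143,In,77.40,In,NA,NA,17.07,Out,198,In,110,In,63,Out,
79-01-6,Trichloroethylene,43.0,7.91,In,36.10,In,11.08,Out,5.27,Out,8.51,In,12.80,In,10,In,
127-18-4,Tetrachloroethylene,18.2,3.68,In,9.86,In,4.13,Out,21.92,In,20.5,In,21.7,In,4.6,In,
75-07-0,Acetaldehyde,12418,32.6,NA,829,In,583,In,117,Out,126,Out,-451,Out,NA,NA,fused cells: ECOSAR AD token absent in source; TEST read as 829
732-26-3,"2,4,6-Tri-tert-butylphenol",0.072,0.108,In,0.0936,In,0.806,In,19.23,Out,3.16,Out,-3.32,Out,0.16,In,
68937-41-7,Isopropylphenyl phosphate,1.5,0.0044,Out,0.0115,In,0.00074,Out,0.0002,Out,1.41,In,2.91,In,NA,NA,
50-32-8,Benzo[def]chrysene,0.25,0.0016,Out,0.2,In,0.225,In,0.1512,Out,NA,NA,NA,NA,NA,NA,
120-12-7,Anthracene,0.0356,0.809,In,0.7,In,1.21,In,0.1007,In,0.173,Out,0.055,In,0.8,In,trend AD printed NA with value present; read as In
56-55-3,Benz[a]anthracene,0.14,0.101,Out,0.28,In,0.359,In,0.1239,Out,0.25,Out,NA,NA,0.0074,Out,
53-70-3,"Dibenz[a,h]anthracene",0.000551,0.0044,Out,0.11,In,0.138,In,0.0768,Out,0.198,Out,NA,NA,0.012,Out,
106-46-7,"1,4-Dichlorobenzene",2.2,5.45,In,4.16,In,3.07,In,5.9,In,6.83,In,303,In,3.8,In,
608-93-5,Pentachlorobenzene,0.18,0.203,Out,0.65,In,0.641,In,0.7177,Out,108,In,53.9,In,0.27,In,
71-43-2,Benzene,10,36.9,In,49.1,In,7.65,Out,19.34,Out,181,In,2.26E7,In,16,In,
108-88-3,Toluene,3.78,14.8,In,25,In,5.44,In,15.79,Out,185,In,56.8,In,4.5,In,
115-96-8,Tris(2-chloroethyl) phosphate,170,135,In,0.0403,In,0.0857,In,0.0004,Out,104,Out,113,Out,NA,NA,
117-81-7,Bis(2-ethylhexyl) phthalate,0.37,0.01,Out,0.99,In,7.06,Out,0.0299,Out,0.0363,In,0.0696,In,0.027,Out,
84-74-2,Dibutyl phthalate,0.5,1.75,In,6.61,In,17.5,In,1.742,In,6.38,In,73.6,In,3,In,
85-68-7,Benzyl butyl phthalate,0.74,1.4,In,3.17,In,9.92,In,0.0767,Out,2.84,In,4.96,In,2.5,In,
84-69-5,Diisobutyl phthalate,3,2.17,In,6.44,In,26.2,In,0.1047,Out,0.0204,Out,-0.0906,Out,3.7,In,
78-87-5,"1,2-Dichloropropane",55.9,32.2,In,50.1,In,13.1,Out,150.2,In,15.8,Out,NA,NA,14,In,
75-35-4,"1,1-Dichloroethylene",37,12,In,10.3,In,15.2,Out,19.49,In,75,In,59,In,15,In,
121-14-2,"2,4-Dinitrotoluene",34.9,31.8,In,4.06,In,8.04,In,7.82,Out,7.92,In,30.8,In,0.27,In,
95-53-4,o-Toluidine,0.522,3.3,In,1.49,In,6.82,In,6.48,Out,9.13,Out,11.8,Out,NA,NA,
335-67-1,Pentadecafluorooctanoic acid,202,7.44,In,10.3,In,37.2,In,1.14,Out,1.01E6,Out,1.02E6,Out,NA,NA,
87-86-5,Pentachlorophenol,0.73,0.711,In,0.19,In,0.769,Out,1.29,In,0.748,Out,0.886,Out,0.61,In,
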