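cas,name,exp_lc50,ecosar_lc50,ecosar_ad,test_lc50,test_ad,danish_lc50,danish_ad,vega_lc50,vega_ad,read_across_lc50,read_across_ad,trend_analysis_lc50,trend_analysis_ad,kate_lc50,kate_ad,note
120-82-1,"1,2,4-Trichlorobenzene",0.7,2.77,In,1.84,In,1.45,In,2.67,In,15.3,In,244,In,2.4,In,
81-15-2,Musk xylene,0.2,6.12,In,0.07,In,1.03,In,10.1,In,1.5,In,32,In,NA,NA,
75-09-2,Dichloromethane,330,273,In,317,In,NA,NA,251,In,2770,In,329,In,85,In,fused cells: trend/KATE read as 329/85; one AD token lost in source
50-00-0,Formaldehyde,23.9,11.2,In,NA,NA,NA,NA,122,In,26,In,141,In,NA,NA,
77-47-4,Hexachlorocyclopentadiene,0.007,0.217,In,0.33,In,0.25,Out,0.0227,In,0.164,Out,NA,NA,NA,NA,
25637-99-4,Hexabromocyclododecane,0.0025,0.0037,Out,0.045,In,0.0013,Out,0.0135,Out,575,Out,411,In,0.0039,Out,
91-20-3,Naphthalene,0.96,9.39,In,7.27,In,5.07,In,3.74,In,48,In,901,In,6.8,In,
1763-23-1,Heptadecafluorooctanesulfonic acid,68,23.7,In,0.57,In,177032,In,1.79,Out,47.1,In,237,In,2.6,In,
307-35-7,Perfluoro-1-octanesulfonyl fluoride,4.7,0.045,Out,0.24,In,177032,In,0.5612,Out,NA,NA,NA,NA,NA,NA,
2795-39-3,Potassium perufluorooctane sulfonate,9.5,23.7,In,NA,NA,177032,In,NA,NA,111,In,299,In,NA,NA,
25154-52-3,Nonylphenol,0.128,0.068,In,0.63,In,0.11,Out,0.5702,In,20.4,In,51.3,In,0.11,In,
9016-45-9,Nonylphenoxypoly(ethyleneoxy)ethanol,5,0.274,Out,0.72,In,0.417,In,0.592,Out,22.4,In,4.1,In,0.35,Out,
67-66-3,Chloroform,121,2464,In,72.24,In,NA,NA,100.1,In,672,In,319,In,53,In,fused cell: exp/ECOSAR read as 121/2464; advisory row
79-01-6,Trichloroethylene,44.5,29.48,In,30.49,In,9.95,Out,31.25,In,18.3,In,20.3,In,20,In,
1163-19-5,Decabromodiphenyl oxide,0.183,6.6E-7,Out,6.4E-4,In,0.0004,Out,0.7998,Out,0.689,Out,NA,NA,2.0E-6,Out,
127-18-4,Tetrachloroethylene,8.4,4.27,In,15.65,In,2.86,Out,11.3,In,18.3,In,20.3,In,11,In,
75-07-0,Acetaldehyde,30.8,29,In,36.99,In,134,Out,126.79,In,41.1,In,169,In,NA,NA,fused cell: exp/ECOSAR read as 30.8/29; advisory row
732-26-3,"2,4,6-Tri-tert-butylphenol",0.048,0.034,In,0.21,In,0.053,Out,0.8443,In,40.9,In,233,In,NA,NA,
68937-41-7,Isopropylphenyl phosphate,10.8,0.0045,Out,0.0184,In,0.0017,Out,3.75,In,84.2,In,89.8,In,0.0011,Out,VEGA AD printed as garbled token; read as In
120-12-7,Anthracene,2.78,1.15,In,0.6,In,1.2,In,1.42,In,4480,In,6880,In,1.6,In,
106-46-7,"1,4-Dichlorobenzene",1.24,8.52,In,4.19,In,5.51,In,5.41,In,23.3,In,248,In,5.8,In,
608-93-5,Pentachlorobenzene,0.31,0.266,Out,0.41,In,0.12,In,0.316,In,22,In,76.7,In,0.38,In,
118-74-1,Hexachlorobenzene,0.119,0.0068,Out,0.14,In,0.027,In,0.5434,In,41.8,In,110,In,0.2,In,
71-43-2,Benzene,5.3,65.1,In,39.35,In,26.7,Out,30.39,In,77.2,In,270,In,40,In,fused cell: exp/ECOSAR read as 5.3/65.1 (5.3 per validation note)
108-88-3,Toluene,5.5,24.8,In,35.5,In,19.8,In,8.37,In,104,In,152,In,20,In,fused cell: exp/ECOSAR read as 5.5/24.8
115-96-8,Tris(2-chloroethyl) phosphate,66,62.5,In,14.5,In,5.57,Out,2.38,Out,64.3,In,124,In,NA,NA,
117-81-7,Bis(2-ethylhexyl) phthalate,0.16,0.0097,Out,0.33,In,0.0027,Out,54.09,In,204,In,173,In,0.011,Out,
84-74-2,Dibutyl phthalate,0.48,1.11,In,1.11,In,0.339,In,1.13,In,0.408,In,60.9,In,1.3,In,
85-68-7,Benzyl butyl phthalate,0.51,0.911,In,0.47,In,0.123,In,0.5976,In,110,In,116,In,1.1,Out,
84-69-5,Diisobutyl phthalate,0.9,1.36,In,4.16,In,0.568,In,1.12,In,3.81,In,-28.9,In,1.6,In,
78-87-5,"1,2-Dichloropropane",133,55.4,In,61.8,In,42.3,Out,45.18,In,71.3,In,284,In,60,In,
75-35-4,"1,1-Dichloroethylene",107.9,14.8,In,64.1,In,49.1,Out,36.59,In,90.2,In,101,In,67,In,
121-14-2,"2,4-Dinitrotoluene",31,4.2,In,5.59,In,15.1,In,11.07,In,11,In,50.9,In,0.38,In,fused cell: exp/ECOSAR read as 31/4.2
95-53-4,o-Toluidine,81.3,75.2,In,64.7,In,42.7,In,47.81,In,25.6,In,144,In,82,In,
335-67-1,Pentadecafluorooctanoic acid,157,10.1,In,3.62,In,133766,In,10.1,Out,1070,Out,1040,Out,1.2,In,
87-68-3,"Hexachlorobuta-1,3-diene",0.0949,0.171,In,0.56,In,2.6,Out,0.0252,In,NA,NA,NA,NA,NA,NA,
87-86-5,Pentachlorophenol,0.25,0.477,In,0.37,In,0.174,In,0.3362,In,20.3,In,10.8,In,0.73,In,
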