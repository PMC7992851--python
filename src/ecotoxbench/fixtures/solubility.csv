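endpoint,name,water_solubility,exp_lc50,n_models_incorrect
daphnia,Anthracene,0.047,0.0356,4
daphnia,Dibutyl phthalate,11.2,0.5,4
fish,Musk xylene,0.15,0.2,3
fish,Heptadecafluorooctanesulfonic acid,0.106,68,3
fish,"2,4,6-Tri-tert-butylphenol",0.063,0.048,3
fish,Benzene,1880,5.3,3
fish,Bis(2-ethylhexyl) phthalate,0.27,0.16,3
fish,Pentadecafluorooctanoic acid,0.48,157,4
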