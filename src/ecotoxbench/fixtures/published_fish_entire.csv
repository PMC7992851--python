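metric,ECOSAR,TEST,DANISH,VEGA,READ_ACROSS,TREND_ANALYSIS,KATE
n_missing,0,2,3,1,2,4,9
n_correct,20,17,17,17,14,10,10
n_incorrect,17,18,17,19,21,23,18
total_accuracy_pct,54,49,50,47,40,30,36
predictive_power_pct,54,46,46,46,38,27,27
r2_class,0.50,0.39,0.38,0.43,0.17,0.10,0.25
fold10_pct,68,80,65,81,57,36,71
fold100_pct,89,89,79,94,83,48,86
fold1000_pct,92,97,85,97,94,76,89
r2_log10,0.31,0.35,0.27,0.34,0.32,0.03,0.21
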