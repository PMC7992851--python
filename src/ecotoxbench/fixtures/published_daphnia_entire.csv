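metric,ECOSAR,TEST,DANISH,VEGA,READ_ACROSS,TREND_ANALYSIS,KATE
n_missing,0,4,3,2,2,6,12
n_correct,24,21,20,18,16,14,21
n_incorrect,13,12,14,17,19,17,4
total_accuracy_pct,65,64,59,51,46,45,84
predictive_power_pct,65,57,54,49,43,38,57
r2_class,0.46,0.46,0.37,0.29,0.51,0.33,0.65
fold10_pct,76,67,68,63,49,45,80
fold100_pct,86,91,91,80,83,55,96
fold1000_pct,97,97,94,94,94,81,100
r2_log10,0.40,0.42,0.38,0.13,0.42,0.40,0.68
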