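metric,ECOSAR,TEST,DANISH,VEGA,READ_ACROSS,TREND_ANALYSIS,KATE
n_inside_ad,27,22,22,10,21,22,19
n_outside_or_missing,10,4,15,27,16,15,18
n_correct,17,21,12,6,6,9,15
n_incorrect,10,12,10,4,15,13,4
total_accuracy_pct,63,64,55,60,29,41,79
r2_class,0.40,0.46,0.28,0.58,0.29,0.54,0.53
fold10_pct,85,67,59,100,52,55,89
fold100_pct,96,91,91,100,86,64,95
fold1000_pct,100,97,96,100,95,96,100
rmse_log10,0.82,0.91,1.24,0.48,1.49,2.06,0.70
r2_log10,0.51,0.42,0.43,0.82,0.35,0.36,0.51
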