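metric,ECOSAR,TEST,DANISH,VEGA,READ_ACROSS,TREND_ANALYSIS,KATE
n_inside_ad,29,22,19,29,31,30,22
n_outside_or_missing,8,15,18,8,6,6,15
n_correct,16,9,11,16,11,8,8
n_incorrect,13,13,8,13,20,23,14
total_accuracy_pct,55,41,58,55,35,26,36
r2_class,0.66,0.41,0.58,0.57,0.07,0.06,0.35
fold10_pct,83,82,74,90,55,42,86
fold100_pct,100,95,79,97,81,55,95
fold1000_pct,100,100,84,100,94,84,100
rmse_log10,0.71,0.87,1.83,0.75,1.47,2.09,0.80
r2_log10,0.68,0.52,0.57,0.68,0.14,0.00,0.50
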