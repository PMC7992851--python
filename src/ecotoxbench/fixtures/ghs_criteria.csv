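code,label,lower_mg_l,upper_mg_l
1,very_toxic,0,1
2,toxic,1,10
3,harmful,10,100
4,not_harmful,100,inf
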