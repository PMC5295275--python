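age_lower,age_upper,body_weight_kg,intake_rate,intake_units
0,2,11.4,9.2,m3/day
2,10,26.0,12.8,m3/day
10,20,58.0,17.2,m3/day
20,60,80.0,16.0,m3/day
60,,75.0,14.2,m3/day
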