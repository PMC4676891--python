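age_band,population
40-49,8753000
50-59,6413000
60-69,4964000
70-79,2988000
80+,1233000
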