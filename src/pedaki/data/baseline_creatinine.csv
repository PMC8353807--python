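sex,age_min_months,age_max_months,scr_mgdl
F,1,12,0.25
F,12,24,0.30
F,24,60,0.35
F,60,120,0.42
F,120,156,0.52
F,156,192,0.60
F,192,253,0.66
M,1,12,0.26
M,12,24,0.31
M,24,60,0.37
M,60,120,0.45
M,120,156,0.57
M,156,192,0.72
M,192,253,0.85
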