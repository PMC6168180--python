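food,outcome,rr_per_unit,unit_g_per_day,ref_age,age_attenuation,pathway
fruits,chd,0.95,100,50,0.15,direct
fruits,stroke,0.92,100,50,0.15,direct
vegetables,chd,0.90,100,50,0.15,direct
vegetables,stroke,0.93,100,50,0.15,direct
nuts,chd,0.96,10,50,0.15,direct
whole_grains,chd,0.95,50,50,0.15,direct
whole_grains,diabetes,0.88,50,50,0.15,direct
fish,chd,0.94,100,50,0.15,direct
plant_oils,chd,0.95,10,50,0.15,direct
ssb,chd,1.17,248,50,0.15,direct
ssb,stroke,1.07,248,50,0.15,direct
ssb,diabetes,1.13,248,50,0.15,direct
processed_meat,chd,1.27,50,50,0.15,direct
processed_meat,diabetes,1.19,50,50,0.15,direct
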