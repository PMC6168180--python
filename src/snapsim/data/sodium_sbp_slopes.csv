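age_band,race,hypertensive,slope_mmhg_per_g
35-49,nh_black,no,1.8
35-49,nh_black,yes,2.8
35-49,other,no,1.0
35-49,other,yes,2.0
50-64,nh_black,no,2.8
50-64,nh_black,yes,3.8
50-64,other,no,2.0
50-64,other,yes,3.0
65plus,nh_black,no,3.8
65plus,nh_black,yes,4.8
65plus,other,no,3.0
65plus,other,yes,4.0
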