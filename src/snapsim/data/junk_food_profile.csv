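component,delta_per_gram
fruits,-0.12
vegetables,-0.15
whole_grains,0.03
nuts,-0.010
fish,-0.015
plant_oils,-0.020
processed_meat,0.05
ssb,0.50
sodium,0.0035
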