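age_band,adiposity,slope_kg_m2_per_serving
lt50,normal,0.10
lt50,overweight_obese,0.23
ge50,normal,0.05
ge50,overweight_obese,0.12
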