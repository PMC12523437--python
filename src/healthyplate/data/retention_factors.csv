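profile,yield_factor,thiamine_mg,riboflavin_mg,niacin_mg_ne,vitamin_b6_mg,folic_acid_ug,vitamin_b12_ug,ascorbic_acid_mg,vitamin_a_ug_re,vitamin_e_mg_ate,potassium_g,magnesium_mg
raw,1.0,,,,,,,,,,,
boiled_vegetable,0.95,0.75,0.80,0.75,0.75,0.55,,0.50,0.90,0.90,0.70,0.75
boiled_grain,2.0,0.75,0.85,0.80,0.85,0.70,,1.0,1.0,0.95,0.85,0.90
grilled_meat,0.75,0.80,0.90,0.85,0.80,0.85,0.80,0.70,0.90,0.90,0.90,0.95
baked_fish,0.85,0.85,0.90,0.90,0.85,0.90,0.90,0.80,0.90,0.95,0.95,0.95
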