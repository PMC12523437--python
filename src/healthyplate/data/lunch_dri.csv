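nutrient,female_14-19,female_20-29,female_30-39,female_40-49,female_50-59,female_60-69,female_70+,male_14-19,male_20-29,male_30-39,male_40-49,male_50-59,male_60-69,male_70+
energy_kcal,1003,1003,1003,866,866,866,866,1368,1322,1322,1322,1048,1048,1048
protein_g,22,23,25,25,25,25,25,30,29,32,32,32,32,32
fat_g,37,37,37,32,32,32,32,51,48,48,48,39,39,39
carbohydrate_g,119,119,119,104,104,104,104,163,156,156,156,126,126,126
fibre_g,13,13,13,11,11,11,11,20,20,20,20,15,15,15
calcium_mg,360,297,297,297,297,313,313,360,297,297,297,297,313,313
magnesium_mg,133,133,133,133,133,125,125,156,156,156,156,156,156,156
phosphorus_mg,361,316,316,316,316,316,316,361,316,316,316,316,316,316
sodium_mg,796,796,796,796,796,796,796,796,796,796,796,796,796,796
potassium_g,1.71,1.71,1.71,1.71,1.71,1.71,1.71,1.71,1.71,1.71,1.71,1.71,1.71,1.71
iron_mg,7.69,9.23,9.23,9.23,7.69,4.61,4.61,5.64,4.66,4.66,4.66,4.66,4.66,4.66
zinc_mg,4.37,3.88,3.88,3.88,3.88,3.88,3.40,5.34,5.34,5.34,5.34,5.34,5.34,5.34
thiamine_mg,0.58,0.58,0.58,0.58,0.58,0.52,0.52,0.63,0.63,0.63,0.63,0.63,0.58,0.58
riboflavin_mg,0.44,0.44,0.44,0.44,0.44,0.44,0.44,0.55,0.55,0.55,0.55,0.55,0.55,0.51
niacin_mg_ne,7.94,7.41,7.41,7.41,7.41,7.41,7.41,9.00,9.00,9.00,9.00,9.00,8.47,8.47
vitamin_b6_mg,0.59,0.64,0.64,0.64,0.64,0.73,0.73,0.73,0.83,0.83,0.83,0.83,0.83,0.83
folic_acid_ug,159,159,159,159,159,159,159,159,159,159,159,159,159,159
vitamin_b12_ug,1.14,1.14,1.14,1.14,1.14,1.14,1.14,1.14,1.14,1.14,1.14,1.14,1.14,1.14
ascorbic_acid_mg,37,37,37,37,37,37,37,37,37,37,37,37,37,37
vitamin_a_ug_re,313,313,313,313,313,313,313,361,361,361,361,361,361,361
vitamin_d_ug,5.39,5.39,5.39,5.39,5.39,5.39,6.47,5.39,5.39,5.39,5.39,5.39,5.39,6.47
vitamin_e_mg_ate,5.46,5.46,5.46,5.46,5.46,5.46,5.46,6.45,6.45,6.45,6.45,6.45,6.45,6.45
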