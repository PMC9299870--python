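nutrient,western_highlands_recall24h,western_highlands_hces,eastern_uganda_recall24h,eastern_uganda_hces,western_uganda_recall24h,western_uganda_hces,sylhet_recall24h,sylhet_hces,kitui_recall24h,kitui_hces,isiolo_recall24h,isiolo_hces,marsabit_recall24h,marsabit_hces,vihiga_recall24h,vihiga_hces
fat,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
calcium,0,0,1,1,1,1,1,1,1,1,1,1,0,1,1,1
folate,0,0,1,1,0,0,1,1,0,0,0,0,1,1,0,0
iron,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
niacin,0,0,1,0,0,0,0,0,1,1,1,1,1,1,1,0
protein,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
riboflavin,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
thiamin,0,0,1,0,0,0,0,0,1,0,1,1,0,0,1,0
vitamin_a,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0
vitamin_b12,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0
vitamin_b6,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0
vitamin_c,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0
zinc,0,0,1,1,1,1,1,1,1,1,1,1,1,1,1,1
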