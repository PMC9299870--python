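subgroup,western_highlands_recall24h,western_highlands_hces,eastern_uganda_recall24h,eastern_uganda_hces,western_uganda_recall24h,western_uganda_hces,sylhet_recall24h,sylhet_hces,kitui_recall24h,kitui_hces,isiolo_recall24h,isiolo_hces,marsabit_recall24h,marsabit_hces,vihiga_recall24h,vihiga_hces
"Butter, ghee, margarine (unfortified)",.,0,.,.,0,0,.,.,.,0,0,0,0,0,0,0
Margarine (fortified),.,.,.,0,0,0,.,.,2,.,0,.,0,.,0,0
Vegetable oil (fortified),.,.,0,0,0,0,.,.,0,0,0,0,0,1,0,0
Vegetable oil (unfortified),0,0,.,.,.,.,0,0,.,.,.,.,.,.,0,0
Sugar,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Refined grain bread,0,5,6,8,6,6,.,.,.,0,.,0,.,.,0,1
Sweet bakery products,.,.,0,.,.,.,0,.,.,.,.,0,.,.,0,0
Sugar-sweetened drinks,0,0,.,0,0,0,.,.,.,0,.,.,.,.,.,0
Broths or soups,0,2,0,.,.,.,.,.,4,.,.,.,.,.,0,.
Fluid or powdered milk,0,0,6,4,5,5,4,6,5,3,10,2,10,2,4,2
Other fruit,0,0,0,0,1,1,0,0,.,0,0,0,.,.,0,0
Vitamin A-source fruit,.,0,.,0,0,0,.,0,.,10,.,0,.,.,.,2
Vitamin C-rich fruit,0,0,0,1,0,0,1,1,.,0,.,.,.,.,0,1
Enriched/fortified grains and products,11,6,.,.,.,.,.,.,.,.,.,.,4,.,.,.
Refined grains and products (unfortified),8,8,0,0,0,0,.,.,5,0,0,0,0,0,0,0
Whole grains and products (unfortified),3,8,5,7,5,5,8,7,7,7,5,7,2,7,7,7
Breastmilk,10,10,10,10,10,10,10,10,10,10,10,10,10,10,10,10
"Beans, lentils, peas",2,4,3,3,7,7,3,2,6,7,8,8,8,6,4,7
"Nuts, seeds, not sweet",.,.,5,0,0,0,.,0,.,.,.,.,.,.,.,1
Eggs,2,2,.,8,0,0,1,0,.,0,0,.,.,.,.,0
Fish without bones,.,.,.,0,0,0,0,2,.,.,.,.,.,.,.,0
Organ meat,.,4,.,.,.,.,.,.,.,0,.,7,.,.,.,5
Pork,.,0,.,0,0,0,.,.,.,.,.,.,.,.,.,.
"Poultry, rabbit",0,0,.,0,.,.,.,.,.,.,.,.,.,.,.,0
Red meat,.,0,.,2,7,7,.,.,.,1,.,3,5,8,2,2
"Small, whole fish",.,.,6,7,0,0,3,2,.,.,.,.,.,.,7,2
Other composites,.,.,.,.,.,.,0,0,.,.,.,.,.,.,.,.
Other starchy plant foods,0,0,8,0,5,5,6,0,3,2,5,2,5,2,3,5
Condiment vegetables,0,0,0,0,0,0,0,1,.,.,.,.,.,.,.,0
Other vegetables,0,3,0,0,1,4,7,6,1,3,3,1,0,2,4,2
Vitamin A-source dark green leafy vegetables,5,5,8,3,7,6,7,9,10,8,7,5,.,.,9,10
Vitamin A-source other vegetables,0,0,0,2,0,0,.,.,.,.,.,.,.,.,1,0
Vitamin C-rich vegetables,0,0,1,2,7,7,0,7,6,0,.,1,2,.,0,0
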