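metric,western_highlands,eastern_uganda,western_uganda,sylhet,kitui,isiolo,marsabit,vihiga
n_foods,68.0,46.0,46.0,76.0,41.0,34.0,24.0,55.0
n_subgroups,31.0,26.0,28.0,27.0,21.0,23.0,15.0,30.0
n_groups,15.0,13.0,13.0,14.0,12.0,14.0,10.0,14.0
median_portion_ratio,1.0,1.19,1.39,1.14,0.62,0.78,0.54,1.0
food_agreement,39.7,45.7,47.8,38.2,34.1,44.1,50.0,38.2
subgroup_agreement,71.0,57.7,57.1,66.7,61.9,47.8,73.3,66.7
group_agreement,86.7,84.6,84.6,78.6,83.3,57.1,90.0,78.6
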