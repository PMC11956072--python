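code,label,category,table4_order
grain_based_staple_foods,Grain-based staple foods,promote,1
whole_grains,Whole grains,promote,2
roots_and_tubers,Roots and tubers,promote,3
pulses_legumes,Pulses/legumes,promote,4
nuts_and_seeds,Nuts and seeds,promote,5
vitamin_a_rich_orange_vegetables,Vitamin A-rich orange vegetables,promote,6
dark_green_leafy_vegetables,Dark green leafy vegetables,promote,7
other_vegetables,Other vegetables,promote,8
vitamin_a_rich_fruits,Vitamin A-rich fruits,promote,9
citrus_fruits,Citrus fruits,promote,10
other_fruits,Other fruits,promote,11
eggs,Eggs,promote,12
cheese,Cheese,promote,13
yogurt,Yogurt,promote,14
milk,Milk,promote,15
poultry,Poultry,promote,16
fish_and_seafood,Fish and seafood,promote,17
unprocessed_red_meat_ruminants,Unprocessed red meat (ruminants),limit,18
unprocessed_red_meat_non_ruminants,Unprocessed red meat (non-ruminants),limit,19
processed_meats,Processed meats,limit,20
baked_grain_based_sweets,Baked/grain-based sweets,limit,21
other_sweets,Other sweets,limit,22
salty_snacks,Salty snacks,limit,23
instant_noodles,Instant noodles,limit,24
deep_fried_foods,Deep-fried foods,limit,25
fast_foods,Fast foods,limit,26
sweet_tea_coffee_cocoa,Sweet tea/coffee/cocoa,limit,27
fruit_juice_fruit_flavoured_drinks,Fruit juice/fruit-flavoured drinks,limit,28
soft_drinks_and_energy_sports_drinks,Soft drinks and energy/sports drinks,limit,29
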