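item_id,name,intake_group,group,efp_category,pyramid_group,energy_kcal_per_100g,protein_g_per_100g,nitrogen_factor,is_beverage,is_composite,density_g_per_ml
pita_bread,Pita bread,bread_cereals_grains,grains_cereals,vegetable,grains_cereals,320,7.42581,5.83,0,0,1.0
white_rice,White rice (cooked),bread_cereals_grains,grains_cereals,vegetable,grains_cereals,200,7.42581,5.83,0,0,1.0
pasta,Pasta (cooked),bread_cereals_grains,grains_cereals,vegetable,grains_cereals,220,7.42581,5.83,0,0,1.0
bulgur,Bulgur (cooked),bread_cereals_grains,grains_cereals,vegetable,grains_cereals,220,7.42581,5.83,0,0,1.0
lentils,Lentils (cooked),legumes,legumes,vegetable,protein_foods,115,6.91847,6.25,0,0,1.0
chickpeas,Chickpeas (cooked),legumes,legumes,vegetable,protein_foods,130,6.91847,6.25,0,0,1.0
fava_beans,Fava beans (cooked),legumes,legumes,vegetable,protein_foods,100,6.91847,6.25,0,0,1.0
almonds,Almonds,nuts_seeds,olives_nuts_seeds,vegetable,protein_foods,580,25.116,5.46,0,0,1.0
walnuts,Walnuts,nuts_seeds,olives_nuts_seeds,vegetable,protein_foods,650,25.116,5.46,0,0,1.0
green_olives,Green olives,nuts_seeds,olives_nuts_seeds,vegetable,protein_foods,145,25.116,5.46,0,0,1.0
potato,Potato,starchy_vegetables,vegetables,vegetable,fruits_vegetables,90,1.73018,6.25,0,0,1.0
corn,Corn,starchy_vegetables,vegetables,vegetable,fruits_vegetables,95,1.73018,6.25,0,0,1.0
tomato,Tomato,vegetables,vegetables,vegetable,fruits_vegetables,20,1.73018,6.25,0,0,1.0
cucumber,Cucumber,vegetables,vegetables,vegetable,fruits_vegetables,16,1.73018,6.25,0,0,1.0
leafy_greens,Leafy greens,vegetables,vegetables,vegetable,fruits_vegetables,30,1.73018,6.25,0,0,1.0
tabbouleh,Tabbouleh (composite dish),vegetables,vegetables,vegetable,fruits_vegetables,,,,0,1,1.0
milk,Milk,dairy_products,milk_yogurt_labneh,animal,milk_yogurt,61,4.70287,6.38,0,0,1.0
yogurt,Yogurt,dairy_products,milk_yogurt_labneh,animal,milk_yogurt,61,4.70287,6.38,0,0,1.0
labneh,Labneh,dairy_products,milk_yogurt_labneh,animal,milk_yogurt,105,4.70287,6.38,0,0,1.0
white_cheese,White cheese,dairy_products,cheese,animal,protein_foods,290,11.06558,6.38,0,0,1.0
beef,Beef,red_meat,meat_red_processed,animal,red_meat_sweets,250,25.73116,6.25,0,0,1.0
lamb,Lamb,red_meat,meat_red_processed,animal,red_meat_sweets,280,25.73116,6.25,0,0,1.0
mortadella,Mortadella,processed_meat,meat_red_processed,animal,red_meat_sweets,310,25.73116,6.25,0,0,1.0
chicken,Chicken,poultry,poultry,animal,protein_foods,190,25.39462,6.25,0,0,1.0
turkey,Turkey,poultry,poultry,animal,protein_foods,160,25.39462,6.25,0,0,1.0
tuna,Tuna (canned),fish,fish,animal,protein_foods,130,24.69271,6.25,0,0,1.0
sardines,Sardines,fish,fish,animal,protein_foods,165,24.69271,6.25,0,0,1.0
eggs,Eggs,eggs,eggs,animal,protein_foods,143,12.37067,6.25,0,0,1.0
apple,Apple,fruits,fruits,vegetable,fruits_vegetables,52,0.83382,6.25,0,0,1.0
banana,Banana,fruits,fruits,vegetable,fruits_vegetables,89,0.83382,6.25,0,0,1.0
orange,Orange,fruits,fruits,vegetable,fruits_vegetables,47,0.83382,6.25,0,0,1.0
orange_juice,Fresh orange juice,fresh_juices,fruits,vegetable,fruits_vegetables,45,0.83382,6.25,1,0,1.0
baklava,Baklava,sweets,sweets_snacks_added_sugars,other,red_meat_sweets,430,4.07625,6.25,0,0,1.0
chocolate,Chocolate,sweets,sweets_snacks_added_sugars,other,red_meat_sweets,530,4.07625,6.25,0,0,1.0
biscuits,Biscuits,sweets,sweets_snacks_added_sugars,other,red_meat_sweets,450,4.07625,6.25,0,0,1.0
sugar,Table sugar,added_sugars,sweets_snacks_added_sugars,other,red_meat_sweets,387,4.07625,6.25,0,0,1.0
honey,Honey,added_sugars,sweets_snacks_added_sugars,other,red_meat_sweets,304,4.07625,6.25,0,0,1.0
olive_oil,Olive oil,added_fats_oils,olive_oil,vegetable,olive_oil,884,0.0,6.25,0,0,1.0
vegetable_oil,Vegetable oil,added_fats_oils,added_fats_oils,other,,884,0.0,6.25,0,0,1.0
mixed_herbs,Mixed fresh herbs,herbs_spices,herbs_spices,other,,40,0.0,6.25,0,0,1.0
spices_mix,Spices,herbs_spices,herbs_spices,other,,60,0.0,6.25,0,0,1.0
coffee,Coffee (prepared),hot_beverages,hot_beverages,other,,5,0.0,6.25,1,0,1.0
tea,Tea (prepared),hot_beverages,hot_beverages,other,,2,0.0,6.25,1,0,1.0
drinking_water,Drinking water,drinking_water,drinking_water,other,,0,0.0,6.25,1,0,1.0
cola,Cola,non_alcoholic_beverages,sugar_sweetened_beverages,other,,42,0.35396,6.25,1,0,1.0
fruit_drink,Fruit drink,non_alcoholic_beverages,sugar_sweetened_beverages,other,,45,0.35396,6.25,1,0,1.0
beer,Beer,alcoholic_beverages,alcoholic_beverages,other,,43,0.0,6.25,1,0,1.0
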