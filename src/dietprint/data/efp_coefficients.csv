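item_id,water_l_per_kg,ghge_kgco2eq_per_kg,source
pita_bread,1906.7722,2.52223,double-pyramid
white_rice,1906.7722,2.52223,commodity-dataset
pasta,1906.7722,2.52223,double-pyramid
bulgur,1906.7722,2.52223,commodity-dataset
lentils,2568.736,0.74794,double-pyramid
chickpeas,2568.736,0.74794,double-pyramid
fava_beans,2568.736,0.74794,commodity-dataset
almonds,16614.0,6.0,double-pyramid
walnuts,16614.0,6.0,double-pyramid
green_olives,16614.0,6.0,commodity-dataset
potato,102.7397,2.30678,double-pyramid
corn,102.7397,2.30678,commodity-dataset
tomato,102.7397,2.30678,double-pyramid
cucumber,102.7397,2.30678,double-pyramid
leafy_greens,102.7397,2.30678,commodity-dataset
milk,1137.2719,2.02349,double-pyramid
yogurt,1137.2719,2.02349,double-pyramid
labneh,1137.2719,2.02349,commodity-dataset
white_cheese,2352.5203,4.11924,double-pyramid
beef,11749.1564,26.09674,double-pyramid
lamb,11749.1564,26.09674,commodity-dataset
mortadella,11749.1564,26.09674,commodity-dataset
chicken,3864.6595,4.677,double-pyramid
turkey,3864.6595,4.677,commodity-dataset
tuna,2563.6523,4.38982,commodity-dataset
sardines,2563.6523,4.38982,double-pyramid
eggs,3301.3945,4.94827,double-pyramid
apple,629.4256,0.41049,double-pyramid
banana,629.4256,0.41049,commodity-dataset
orange,629.4256,0.41049,double-pyramid
orange_juice,629.4256,0.41049,double-pyramid
baklava,3789.8731,2.72738,recipe-derived
chocolate,3789.8731,2.72738,double-pyramid
biscuits,3789.8731,2.72738,double-pyramid
sugar,3789.8731,2.72738,commodity-dataset
honey,3789.8731,2.72738,commodity-dataset
olive_oil,20660.2954,5.21286,double-pyramid
vegetable_oil,6392.702,3.47524,commodity-dataset
mixed_herbs,0.0,0.0,assumed-zero
spices_mix,0.0,0.0,assumed-zero
coffee,118.6292,0.80464,commodity-dataset
tea,118.6292,0.80464,commodity-dataset
drinking_water,0.0,0.0,assumed-zero
cola,1480.5324,2.12374,double-pyramid
fruit_drink,1480.5324,2.12374,commodity-dataset
beer,0.0,0.0,assumed-zero
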