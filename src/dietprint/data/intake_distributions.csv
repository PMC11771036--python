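intake_group,mean_per_day,sd_per_day,unit
bread_cereals_grains,317.18,134.85,g
legumes,66.85,54.77,g
nuts_seeds,5.0,12.46,g
starchy_vegetables,50.48,43.48,g
vegetables,206.49,117.79,g
dairy_products,184.5,164.72,g
red_meat,41.34,48.39,g
processed_meat,3.11,5.32,g
poultry,34.21,42.34,g
fish,11.39,21.02,g
eggs,22.23,32.6,g
fruits,254.33,284.95,g
fresh_juices,38.0,75.5,ml
sweets,65.36,114.08,g
added_sugars,18.97,22.15,g
added_fats_oils,11.51,11.68,g
herbs_spices,47.87,44.1,g
hot_beverages,546.83,427.36,ml
drinking_water,1440.48,843.19,ml
non_alcoholic_beverages,70.63,120.94,ml
alcoholic_beverages,0.6,5.9,ml
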