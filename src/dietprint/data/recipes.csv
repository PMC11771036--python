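composite_id,ingredient_id,mass_fraction
tabbouleh,bulgur,0.2
tabbouleh,leafy_greens,0.45
tabbouleh,tomato,0.25
tabbouleh,olive_oil,0.1
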