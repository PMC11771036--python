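tiers:
- rank: 1
  groups:
  - fruits_vegetables
- rank: 2
  groups:
  - grains_cereals
- rank: 3
  groups:
  - olive_oil
  - milk_yogurt
  - protein_foods
- rank: 4
  groups:
  - red_meat_sweets
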