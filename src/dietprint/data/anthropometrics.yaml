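male:
  weight_kg:
    mean: 81.8
    sd: 16.6
  height_cm:
    mean: 173.5
    sd: 7.0
female:
  weight_kg:
    mean: 68.3
    sd: 15.1
  height_cm:
    mean: 159.5
    sd: 5.9
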