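gender:
  male: 0.41216216216216217
  female: 0.5878378378378378
age_bands:
- low: 18
  high: 18
  p: 0.04504504504504504
- low: 19
  high: 30
  p: 0.42117117117117114
- low: 31
  high: 50
  p: 0.3918918918918919
- low: 51
  high: 64
  p: 0.14189189189189189
governorate:
  Akkar: 0.06981981981981981
  Mount Lebanon: 0.40315315315315314
  Beqaa: 0.060810810810810814
  North Lebanon: 0.13513513513513514
  Baalbek-Hermel: 0.04504504504504504
  South Lebanon: 0.12387387387387387
  Beirut: 0.07207207207207207
  Nabatiyeh: 0.09009009009009009
marital_status:
  single: 0.45495495495495497
  married: 0.5022522522522522
  widowed: 0.015765765765765764
  divorced: 0.02702702702702703
education:
  illiterate: 0.006756756756756757
  school: 0.39414414414414417
  university: 0.5990990990990991
employment:
  unemployed: 0.49099099099099097
  employed: 0.509009009009009
income_band:
  none: 0.08783783783783784
  lt_1_5m_lbp: 0.13063063063063063
  ge_1_5m_lbp: 0.4752252252252252
  le_300_usd: 0.2072072072072072
  gt_300_usd: 0.0990990990990991
household_size:
  '1': 0.05
  '2': 0.12
  '3': 0.16
  '4': 0.22
  '5': 0.2
  '6': 0.12
  '7': 0.08
  '8': 0.05
n_rooms:
  '2': 0.35
  '3': 0.35
  '4': 0.2
  '5': 0.1
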