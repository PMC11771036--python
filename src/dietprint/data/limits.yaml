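limits:
- metric: water
  value: 786.0
  units: L/cap/day
  citation: per-capita environmental constraint derived from 152-country data
- metric: ghge
  value: 1866.0
  units: g CO2-eq/cap/day
  citation: per-capita environmental constraint derived from 152-country data
- metric: nitrogen
  value: 27.4
  units: g N/cap/day
  citation: per-capita environmental constraint derived from 152-country data
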