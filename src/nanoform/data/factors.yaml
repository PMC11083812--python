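factors:
- name: GMS
  low: 1.5
  high: 2.5
  units: g
- name: P80
  low: 0.6
  high: 1.0
  units: g
- name: CBD
  low: 10.0
  high: 20.0
  units: mg
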