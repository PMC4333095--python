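{
  "name": "ZTRE",
  "left": "C-A/C-C-T/A/G-C-C-T/C",
  "right": "G/A-G-A/T/C-G-T/G-G",
  "gap_min": 0,
  "gap_max": 50
}
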