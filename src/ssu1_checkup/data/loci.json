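{
  "loci": [
    {"name": "C3", "motif_len": 2},
    {"name": "C4", "motif_len": 2},
    {"name": "C5", "motif_len": 2},
    {"name": "C6", "motif_len": 2},
    {"name": "C8", "motif_len": 2},
    {"name": "C9", "motif_len": 2},
    {"name": "C11", "motif_len": 2},
    {"name": "SCAAT1", "motif_len": 3},
    {"name": "SCAAT2", "motif_len": 3},
    {"name": "SCAAT3", "motif_len": 3},
    {"name": "SCAAT5", "motif_len": 3},
    {"name": "SCAAT6", "motif_len": 3},
    {"name": "SCYOR267C", "motif_len": 3},
    {"name": "YKL172W", "motif_len": 2},
    {"name": "YPL009C", "motif_len": 2}
  ]
}
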