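{
  "KDHR": [
    {"HE": 2.2, "HC": 1.5},
    {"HE": 2.3, "HC": 1.1},
    {"HE": 2.0, "HC": 1.2},
    {"HE": 2.4, "HC": 1.6}
  ],
  "PTM": [
    {"HE": 2.9, "HC": 1.7},
    {"HE": 2.8, "HC": 1.9},
    {"HE": 2.6, "HC": 1.5},
    {"HE": 3.1, "HC": 2.0}
  ],
  "Coverage-Soft-Model": [
    {"HE": 1.9, "HC": 1.5},
    {"HE": 2.2, "HC": 1.4},
    {"HE": 2.0, "HC": 1.3},
    {"HE": 2.5, "HC": 1.5}
  ],
  "Herb-Know": [
    {"HE": 3.5, "HC": 1.8},
    {"HE": 3.1, "HC": 2.3},
    {"HE": 2.9, "HC": 1.9},
    {"HE": 3.8, "HC": 2.2}
  ],
  "TPGen": [
    {"HE": 3.7, "HC": 1.8},
    {"HE": 3.2, "HC": 2.2},
    {"HE": 2.9, "HC": 2.1},
    {"HE": 3.6, "HC": 2.5}
  ],
  "GSCCAM": [
    {"HE": 4.3, "HC": 3.5},
    {"HE": 4.2, "HC": 3.4},
    {"HE": 3.9, "HC": 3.6},
    {"HE": 4.2, "HC": 3.7}
  ]
}
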