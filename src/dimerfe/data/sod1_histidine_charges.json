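{
  "_comment": "Reference partial charges (e) for the reparametrized metal-coordinating histidine side chains of holo SOD1: HSN (doubly deprotonated, bridging Cu and Zn), HSDM (delta-protonated, metal-coordinating), HSEM (epsilon-protonated, metal-coordinating). Shipped as reference data; reproducing them requires the external QM targets and subsystem geometry.",
  "HSN":  {"ND1": -0.944, "CG": -0.15, "CE1": 0.75, "HE1": 0.5,  "NE2": -0.7,  "CD2": -0.156, "HD2": -0.4},
  "HSDM": {"ND1": -0.26,  "HD1": 0.42, "CG": 0.05,  "CE1": 0.15, "HE1": 0.23, "NE2": -0.8,  "CD2": 0.12,  "HD2": 0.0},
  "HSEM": {"ND1": -0.8,   "CG": 0.12,  "CE1": 0.15, "HE1": 0.03, "NE2": -0.26, "HE2": 0.42,  "CD2": 0.05,  "HD2": 0.19}
}
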