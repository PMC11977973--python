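{
  "species": ["U", "V"],
  "initial": {"U": 0, "V": 0},
  "reactions": [
    {"name": "produce_U", "reactants": {}, "products": {"U": 1},
     "propensity": "50 / (1 + pow(V / 20, 2))"},
    {"name": "degrade_U", "reactants": {"U": 1}, "products": {}, "rate": 1.0},
    {"name": "produce_V", "reactants": {}, "products": {"V": 1},
     "propensity": "50 / (1 + pow(U / 20, 2))"},
    {"name": "degrade_V", "reactants": {"V": 1}, "products": {}, "rate": 1.0}
  ]
}
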