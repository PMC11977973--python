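{
  "species": ["X"],
  "initial": {"X": 0},
  "reactions": [
    {"name": "birth", "reactants": {}, "products": {"X": 1}, "rate": 10.0},
    {"name": "death", "reactants": {"X": 1}, "products": {}, "rate": 1.0}
  ]
}
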