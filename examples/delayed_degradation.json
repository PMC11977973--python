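{
  "species": ["X"],
  "initial": {"X": 0},
  "reactions": [
    {"name": "birth", "reactants": {}, "products": {"X": 1}, "rate": 5.0},
    {"name": "delayed_death", "reactants": {"X": 1}, "products": {}, "rate": 1.0,
     "delay": {"kind": "completion_only", "value": 2.0}}
  ]
}
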