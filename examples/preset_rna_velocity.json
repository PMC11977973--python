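{"preset": "rna_velocity", "params": {"alpha": 20.0, "beta": 1.0, "gamma": 0.5, "t_switch": 50.0, "tau": 2.0}}
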