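{"preset": "refractory", "params": {"k1": 0.15, "k2": 0.1, "k3": 0.05, "k4": 10.0, "tau": 1.0}}
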