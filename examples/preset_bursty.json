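{"preset": "bursty", "params": {"alpha": 0.0282, "b": 3.46, "tau": 120.0}}
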