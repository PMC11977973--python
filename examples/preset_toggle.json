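{"preset": "toggle", "params": {"alpha": 50.0, "K": 20.0, "n_hill": 2.0, "d": 1.0}}
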