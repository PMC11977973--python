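{"preset": "ast", "params": {"alpha_S": 0.8, "B": 6023.0, "degrader": {"k_deg": 2.0, "tau_S": 1.0}}}
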