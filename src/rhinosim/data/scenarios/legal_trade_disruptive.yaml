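schema_version: 1
name: legal_trade_disruptive
p_a: 0.6
p_m: 0.0
t: 1
disruption: true
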