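schema_version: 1
name: status_quo
p_a: 0.1
p_m: 0.0
t: 0
disruption: false
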