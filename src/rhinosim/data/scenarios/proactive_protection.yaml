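schema_version: 1
name: proactive_protection
p_a: 0.2
p_m: 0.0
t: 0
disruption: false
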