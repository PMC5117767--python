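year,population
2010,4165440162
2020,4581523062
2030,4886846140
2040,5080418644
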