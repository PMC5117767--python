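year,poached,retail_price_usd_per_kg
2009,122,5000
2010,333,10000
2011,341,20000
2012,668,65000
2013,1004,65000
2014,1215,97000
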