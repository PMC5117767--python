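year,bid_zar_per_usd,ask_zar_per_usd,inv_bid
2006,6.75050,6.78812,0.14814
2007,7.03077,7.06926,0.14223
2008,8.23218,8.27505,0.12147
2009,8.40084,8.44468,0.11904
2010,7.30053,7.34412,0.13698
2011,7.23125,7.27131,0.13829
2012,8.19734,8.22357,0.12199
2013,9.63485,9.65134,0.10379
2014,10.68529,10.70243,0.09359
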