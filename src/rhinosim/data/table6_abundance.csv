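year,observed,ci_low,ci_high,predicted
1998,2674,1987,4047,2706
1999,2938,2295,4043,3090
2000,2683,1965,3629,3401
2001,4552,3320,6673,3764
2002,4223,3604,5466,4217
2003,4765,3710,5627,4841
2004,5308,3631,6434,5465
2005,6974,6026,8022,5990
2006,8893,7286,10902,6704
2007,9119,7665,12438,7677
2008,11498,9734,15619,8601
2009,,,,
2010,10466,9320,11360,10929
2011,,,,
2012,10495,8510,12492,8453
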