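year,role,unit,low_usd,high_usd
2006,poacher_water_carrier,per_hunt,89,356
2006,poacher_axe_carrier,per_hunt,89,356
2006,poacher_shooter,per_hunt,89,356
2006,middleman,per_kg,3703,5185
2008,poacher_water_carrier,per_hunt,194,607
2008,poacher_axe_carrier,per_hunt,194,607
2008,poacher_shooter,per_hunt,583,1822
2008,middleman,per_kg,4252,6317
2010,poacher_water_carrier,per_hunt,548,1096
2010,poacher_axe_carrier,per_hunt,548,1096
2010,poacher_shooter,per_hunt,1644,3287
2010,middleman,per_kg,5479,8903
2012,poacher_water_carrier,per_hunt,488,2074
2012,poacher_axe_carrier,per_hunt,488,2074
2012,poacher_shooter,per_hunt,1464,6222
2012,transporter,per_event,488,976
2012,middleman,per_kg,9149,18299
2013,poacher_water_carrier,per_hunt,830,1661
2013,poacher_axe_carrier,per_hunt,830,1661
2013,poacher_shooter,per_hunt,2491,4982
2013,transporter,per_event,415,830
2013,middleman,per_kg,6227,12455
2014,poacher_water_carrier,per_hunt,749,7113
2014,poacher_axe_carrier,per_hunt,749,7113
2014,poacher_shooter,per_hunt,2246,21338
2014,poacher_water_carrier,per_kg,1497,1871
2014,poacher_axe_carrier,per_kg,1497,1871
2014,poacher_shooter,per_kg,4492,5615
2014,transporter,per_event,374,749
2014,exporter_airport,per_item,2808,2808
2014,exporter_harbor,per_item,0,0
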