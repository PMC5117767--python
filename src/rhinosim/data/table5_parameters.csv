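name,notation,units,value,low,high
trader_learning_rate,r_a,unit_interval,0.4,0.2,0.6
consumer_reserve_price,reserveprice,usd,60000,50000,70000
legal_trader_max_capacity,maxcap1,horns,35,30,40
illegal_trader_max_capacity,maxcap2,horns,35,30,40
weekly_food_intake,wfi,kg,140,120,160
life_expectancy,le,years,38,32,42
maturation_age,ma,years,4,3.5,4.5
max_energetic_budget,meb,weeks,5,4.5,5.5
mean_energetic_budget,meaneb,weeks,4,3.5,4.5
juvenile_energetic_budget,jeb,weeks,3,2.5,3.5
intercalving_interval,intercalv,years,2.5,2.5,5
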