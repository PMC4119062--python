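seedling,group,hypocotyl_length_mm,period_min,length_mm,rate_mm_per_min,shape,angle_deg,cw_pct,ccw_pct,ind_pct
1,distilled_water,85,270,18,0.07,0.43,-24,0,69,31
2,distilled_water,60,267,16,0.06,0.21,1,0,33,67
3,distilled_water,80,335,36,0.12,0.31,-3,40,30,30
4,distilled_water,90,293,19,0.07,0.21,-15,11,22,67
5,distilled_water,70,195,9,0.05,0.44,24,0,0,100
6,distilled_water,75,275,9,0.04,0.38,-43,8,0,92
7,distilled_water,65,400,11,0.03,0.54,-36,0,0,100
8,distilled_water,80,260,6,0.02,0.51,-20,0,0,100
9,nutrient_solution,115,225,28,0.11,0.59,0,0,53,47
10,nutrient_solution,105,189,25,0.12,0.35,-17,21,16,63
11,nutrient_solution,112,188,97,0.48,0.57,3,11,74,16
12,nutrient_solution,116,217,42,0.19,0.61,-33,81,6,13
13,nutrient_solution,116,218,48,0.21,0.40,-40,69,6,25
14,nutrient_solution,113,175,73,0.40,0.56,-11,10,86,5
15,nutrient_solution,111,225,47,0.21,0.33,-30,6,81,13
16,nutrient_solution,121,209,99,0.47,0.55,6,76,18,6
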