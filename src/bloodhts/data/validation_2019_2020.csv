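month,actual_2019,forecast_2019,actual_2020,forecast_2020
January,5724,6540,5600,6540
February,8299,7876,7900,7876
March,10812,9268,8850,9267
April,7519,5610,2350,5610
May,9067,7464,2000,7464
June,10439,8377,3500,8377
July,9493,7865,2550,7865
August,6418,5496,3700,5496
September,8474,8117,3850,8117
October,6586,8075,5600,8075
November,5914,6748,5950,6748
December,7131,6507,5900,6507
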