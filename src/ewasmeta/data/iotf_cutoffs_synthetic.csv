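sex,age_years,bmi_underweight,bmi_overweight,bmi_obesity
F,2.0,14.2548,18.8667,20.4987
F,2.5,13.9523,18.5668,20.2149
F,3.0,13.6921,18.3198,19.9880
F,3.5,13.4739,18.1260,19.8186
F,4.0,13.2973,17.9859,19.7077
F,4.5,13.1620,17.8999,19.6560
F,5.0,13.0678,17.8686,19.6646
F,5.5,13.0142,17.8924,19.7343
F,6.0,12.9883,17.9543,19.8467
F,6.5,12.9773,18.0370,19.9830
F,7.0,12.9810,18.1407,20.1435
F,7.5,12.9993,18.2657,20.3288
F,8.0,13.0322,18.4120,20.5391
F,8.5,13.0795,18.5800,20.7748
F,9.0,13.1411,18.7697,21.0364
F,9.5,13.2169,18.9813,21.3241
F,10.0,13.3067,19.2151,21.6386
F,10.5,13.4106,19.4713,21.9801
F,11.0,13.5283,19.7500,22.3491
F,11.5,13.6598,20.0515,22.7461
F,12.0,13.8049,20.3759,23.1715
F,12.5,13.9636,20.7235,23.6258
F,13.0,14.1357,21.0944,24.1094
F,13.5,14.3212,21.4889,24.6229
F,14.0,14.5199,21.9071,25.1666
F,14.5,14.7318,22.3494,25.7412
F,15.0,14.9568,22.8158,26.3470
F,15.5,15.1946,23.3067,26.9847
F,16.0,15.4454,23.8222,27.6548
F,16.5,15.7089,24.3626,28.3578
F,17.0,15.9850,24.9280,29.0943
F,17.5,16.2738,25.5188,29.8648
F,18.0,16.5750,26.1351,30.6699
M,2.0,14.5685,18.9858,20.5035
M,2.5,14.2628,18.6885,20.2232
M,3.0,13.9998,18.4436,19.9989
M,3.5,13.7791,18.2515,19.8314
M,4.0,13.6003,18.1127,19.7215
M,4.5,13.4632,18.0277,19.6700
M,5.0,13.3674,17.9968,19.6780
M,5.5,13.3125,18.0206,19.7461
M,6.0,13.2856,18.0822,19.8563
M,6.5,13.2737,18.1644,19.9900
M,7.0,13.2766,18.2675,20.1476
M,7.5,13.2943,18.3916,20.3295
M,8.0,13.3265,18.5369,20.5359
M,8.5,13.3734,18.7036,20.7674
M,9.0,13.4346,18.8919,21.0243
M,9.5,13.5101,19.1020,21.3069
M,10.0,13.5998,19.3340,21.6157
M,10.5,13.7036,19.5881,21.9511
M,11.0,13.8213,19.8646,22.3135
M,11.5,13.9529,20.1637,22.7034
M,12.0,14.0982,20.4854,23.1211
M,12.5,14.2572,20.8301,23.5671
M,13.0,14.4298,21.1980,24.0418
M,13.5,14.6158,21.5891,24.5458
M,14.0,14.8151,22.0038,25.0795
M,14.5,15.0277,22.4423,25.6433
M,15.0,15.2534,22.9047,26.2378
M,15.5,15.4921,23.3913,26.8635
M,16.0,15.7438,23.9024,27.5208
M,16.5,16.0083,24.4380,28.2104
M,17.0,16.2856,24.9984,28.9326
M,17.5,16.5755,25.5839,29.6881
M,18.0,16.8779,26.1946,30.4774
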