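sex,age_years,L,M,S
F,2.0,-1.6800,16.5437,0.0900
F,2.5,-1.6750,16.2350,0.0918
F,3.0,-1.6700,15.9738,0.0935
F,3.5,-1.6650,15.7600,0.0953
F,4.0,-1.6600,15.5938,0.0970
F,4.5,-1.6550,15.4750,0.0988
F,5.0,-1.6500,15.4038,0.1005
F,5.5,-1.6450,15.3800,0.1023
F,6.0,-1.6400,15.3887,0.1040
F,6.5,-1.6350,15.4150,0.1058
F,7.0,-1.6300,15.4588,0.1075
F,7.5,-1.6250,15.5200,0.1093
F,8.0,-1.6200,15.5988,0.1110
F,8.5,-1.6150,15.6950,0.1128
F,9.0,-1.6100,15.8088,0.1145
F,9.5,-1.6050,15.9400,0.1163
F,10.0,-1.6000,16.0887,0.1180
F,10.5,-1.5950,16.2550,0.1198
F,11.0,-1.5900,16.4387,0.1215
F,11.5,-1.5850,16.6400,0.1233
F,12.0,-1.5800,16.8588,0.1250
F,12.5,-1.5750,17.0950,0.1268
F,13.0,-1.5700,17.3487,0.1285
F,13.5,-1.5650,17.6200,0.1303
F,14.0,-1.5600,17.9087,0.1320
F,14.5,-1.5550,18.2150,0.1338
F,15.0,-1.5500,18.5388,0.1355
F,15.5,-1.5450,18.8800,0.1373
F,16.0,-1.5400,19.2387,0.1390
F,16.5,-1.5350,19.6150,0.1408
F,17.0,-1.5300,20.0087,0.1425
F,17.5,-1.5250,20.4200,0.1443
F,18.0,-1.5200,20.8487,0.1460
M,2.0,-1.6800,16.7838,0.0850
M,2.5,-1.6750,16.4750,0.0868
M,3.0,-1.6700,16.2138,0.0885
M,3.5,-1.6650,16.0000,0.0903
M,4.0,-1.6600,15.8337,0.0920
M,4.5,-1.6550,15.7150,0.0938
M,5.0,-1.6500,15.6437,0.0955
M,5.5,-1.6450,15.6200,0.0973
M,6.0,-1.6400,15.6287,0.0990
M,6.5,-1.6350,15.6550,0.1008
M,7.0,-1.6300,15.6987,0.1025
M,7.5,-1.6250,15.7600,0.1043
M,8.0,-1.6200,15.8387,0.1060
M,8.5,-1.6150,15.9350,0.1078
M,9.0,-1.6100,16.0488,0.1095
M,9.5,-1.6050,16.1800,0.1113
M,10.0,-1.6000,16.3287,0.1130
M,10.5,-1.5950,16.4950,0.1148
M,11.0,-1.5900,16.6788,0.1165
M,11.5,-1.5850,16.8800,0.1183
M,12.0,-1.5800,17.0988,0.1200
M,12.5,-1.5750,17.3350,0.1217
M,13.0,-1.5700,17.5888,0.1235
M,13.5,-1.5650,17.8600,0.1253
M,14.0,-1.5600,18.1487,0.1270
M,14.5,-1.5550,18.4550,0.1288
M,15.0,-1.5500,18.7788,0.1305
M,15.5,-1.5450,19.1200,0.1323
M,16.0,-1.5400,19.4788,0.1340
M,16.5,-1.5350,19.8550,0.1358
M,17.0,-1.5300,20.2488,0.1375
M,17.5,-1.5250,20.6600,0.1393
M,18.0,-1.5200,21.0888,0.1410
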