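# Absorption coefficient of pure water, cm^-1, 650-1800 nm.
# Compiled approximation (PCHIP-densified anchors, see
# scripts/make_extinction_tables.py)
wavelength_nm,mu_a_cm1
650,0.003200
655,0.003234
660,0.003334
665,0.003495
670,0.003714
675,0.003986
680,0.004307
685,0.004673
690,0.005080
695,0.005524
700,0.006000
705,0.006958
710,0.008709
715,0.011042
720,0.013747
725,0.016614
730,0.019432
735,0.021989
740,0.024077
745,0.025484
750,0.026000
755,0.025832
760,0.025376
765,0.024704
770,0.023888
775,0.023000
780,0.022112
785,0.021296
790,0.020624
795,0.020168
800,0.020000
805,0.020428
810,0.021625
815,0.023459
820,0.025796
825,0.028505
830,0.031454
835,0.034510
840,0.037541
845,0.040415
850,0.043000
855,0.045198
860,0.047092
865,0.048821
870,0.050525
875,0.052342
880,0.054412
885,0.056874
890,0.059867
895,0.063529
900,0.068000
905,0.077869
910,0.095395
915,0.117224
920,0.140000
925,0.164357
930,0.192435
935,0.223136
940,0.255362
945,0.288016
950,0.320000
955,0.357909
960,0.400642
965,0.435553
970,0.450000
975,0.445870
980,0.434783
985,0.418696
990,0.399565
995,0.379348
1000,0.360000
1005,0.339136
1010,0.314472
1015,0.288117
1020,0.262181
1025,0.238772
1030,0.220000
1035,0.203860
1040,0.187613
1045,0.172270
1050,0.158840
1055,0.148331
1060,0.141753
1065,0.140041
1070,0.141415
1075,0.144586
1080,0.149342
1085,0.155472
1090,0.162766
1095,0.171012
1100,0.180000
1105,0.194229
1110,0.217374
1115,0.247989
1120,0.284630
1125,0.325848
1130,0.370199
1135,0.416235
1140,0.462512
1145,0.507582
1150,0.550000
1155,0.595494
1160,0.648780
1165,0.706896
1170,0.766878
1175,0.825762
1180,0.880585
1185,0.928384
1190,0.966195
1195,0.991055
1200,1.000000
1205,0.998600
1210,0.994800
1215,0.989200
1220,0.982400
1225,0.975000
1230,0.967600
1235,0.960800
1240,0.955200
1245,0.951400
1250,0.950000
1255,0.954576
1260,0.967824
1265,0.989029
1270,1.017473
1275,1.052439
1280,1.093210
1285,1.139068
1290,1.189298
1295,1.243180
1300,1.300000
1305,1.368881
1310,1.459588
1315,1.572363
1320,1.707448
1325,1.865084
1330,2.045514
1335,2.248978
1340,2.475720
1345,2.725980
1350,3.000000
1355,3.377722
1360,3.925441
1365,4.622931
1370,5.449967
1375,6.386323
1380,7.411773
1385,8.506091
1390,9.649052
1395,10.820431
1400,12.000000
1405,13.429308
1410,15.274462
1415,17.402077
1420,19.678769
1425,21.971154
1430,24.145846
1435,26.069462
1440,27.608615
1445,28.629923
1450,29.000000
1455,28.856000
1460,28.452444
1465,27.832000
1470,27.037333
1475,26.111111
1480,25.096000
1485,24.034667
1490,22.969778
1495,21.944000
1500,21.000000
1505,20.054126
1510,19.014670
1515,17.912214
1520,16.777343
1525,15.640637
1530,14.532681
1535,13.484056
1540,12.525346
1545,11.687133
1550,11.000000
1555,10.402069
1560,9.817151
1565,9.254360
1570,8.722810
1575,8.231616
1580,7.789893
1585,7.406756
1590,7.091318
1595,6.852694
1600,6.700000
1605,6.595736
1610,6.496359
1615,6.401921
1620,6.312469
1625,6.228055
1630,6.148726
1635,6.074534
1640,6.005528
1645,5.941757
1650,5.883271
1655,5.830119
1660,5.782352
1665,5.740018
1670,5.703168
1675,5.671852
1680,5.646117
1685,5.626015
1690,5.611595
1695,5.602907
1700,5.600000
1705,5.607544
1710,5.629850
1715,5.666431
1720,5.716800
1725,5.780469
1730,5.856950
1735,5.945756
1740,6.046400
1745,6.158394
1750,6.281250
1755,6.414481
1760,6.557600
1765,6.710119
1770,6.871550
1775,7.041406
1780,7.219200
1785,7.404444
1790,7.596650
1795,7.795331
1800,8.000000
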