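# Absorption coefficient of pure lipid (soybean-oil-like), cm^-1, 650-1800 nm.
# Compiled approximation (PCHIP-densified anchors, see
# scripts/make_extinction_tables.py)
wavelength_nm,mu_a_cm1
650,0.006000
655,0.006000
660,0.006000
665,0.006000
670,0.006000
675,0.006000
680,0.006000
685,0.006000
690,0.006000
695,0.006000
700,0.006000
705,0.006056
710,0.006208
715,0.006432
720,0.006704
725,0.007000
730,0.007296
735,0.007568
740,0.007792
745,0.007944
750,0.008000
755,0.008000
760,0.008000
765,0.008000
770,0.008000
775,0.008000
780,0.008000
785,0.008000
790,0.008000
795,0.008000
800,0.008000
805,0.008047
810,0.008184
815,0.008408
820,0.008713
825,0.009095
830,0.009550
835,0.010072
840,0.010658
845,0.011302
850,0.012000
855,0.013112
860,0.014963
865,0.017501
870,0.020671
875,0.024422
880,0.028698
885,0.033448
890,0.038617
895,0.044152
900,0.050000
905,0.059342
910,0.073469
915,0.089490
920,0.104513
925,0.115646
930,0.120000
935,0.116865
940,0.108536
945,0.096630
950,0.082763
955,0.068551
960,0.055609
965,0.045553
970,0.040000
975,0.037340
980,0.034951
985,0.032928
990,0.031365
995,0.030357
1000,0.030000
1005,0.030718
1010,0.032640
1015,0.035419
1020,0.038707
1025,0.042157
1030,0.045420
1035,0.048151
1040,0.050000
1045,0.051157
1050,0.052076
1055,0.052812
1060,0.053418
1065,0.053947
1070,0.054453
1075,0.054990
1080,0.055610
1085,0.056368
1090,0.057316
1095,0.058509
1100,0.060000
1105,0.066051
1110,0.079929
1115,0.100194
1120,0.125408
1125,0.154131
1130,0.184923
1135,0.216346
1140,0.246959
1145,0.275324
1150,0.300000
1155,0.323701
1160,0.349564
1165,0.376783
1170,0.404553
1175,0.432070
1180,0.458529
1185,0.483125
1190,0.505054
1195,0.523511
1200,0.537691
1205,0.546789
1210,0.550000
1215,0.541504
1220,0.518639
1225,0.485339
1230,0.445538
1235,0.403169
1240,0.362167
1245,0.326466
1250,0.300000
1255,0.279165
1260,0.258112
1265,0.237410
1270,0.217626
1275,0.199328
1280,0.183084
1285,0.169461
1290,0.159028
1295,0.152352
1300,0.150000
1305,0.151277
1310,0.154985
1315,0.160938
1320,0.168954
1325,0.178846
1330,0.190431
1335,0.203523
1340,0.217938
1345,0.233492
1350,0.250000
1355,0.275614
1360,0.316438
1365,0.369218
1370,0.430699
1375,0.497624
1380,0.566740
1385,0.634791
1390,0.698521
1395,0.754676
1400,0.800000
1405,0.839847
1410,0.880894
1415,0.921871
1420,0.961506
1425,0.998529
1430,1.031671
1435,1.059659
1440,1.081224
1445,1.095094
1450,1.100000
1455,1.097040
1460,1.088808
1465,1.076279
1470,1.060424
1475,1.042219
1480,1.022637
1485,1.002650
1490,0.983233
1495,0.965358
1500,0.950000
1505,0.935755
1510,0.920684
1515,0.904954
1520,0.888735
1525,0.872194
1530,0.855500
1535,0.838821
1540,0.822327
1545,0.806184
1550,0.790561
1555,0.775628
1560,0.761551
1565,0.748500
1570,0.736643
1575,0.726148
1580,0.717184
1585,0.709918
1590,0.704520
1595,0.701158
1600,0.700000
1605,0.716710
1610,0.764931
1615,0.841797
1620,0.944444
1625,1.070009
1630,1.215625
1635,1.378429
1640,1.555556
1645,1.744141
1650,1.941319
1655,2.144227
1660,2.350000
1665,2.555773
1670,2.758681
1675,2.955859
1680,3.144444
1685,3.321571
1690,3.484375
1695,3.629991
1700,3.755556
1705,3.858203
1710,3.935069
1715,3.983290
1720,4.000000
1725,3.925000
1730,3.725000
1735,3.437500
1740,3.100000
1745,2.750000
1750,2.425000
1755,2.162500
1760,2.000000
1765,1.901953
1770,1.809375
1775,1.724609
1780,1.650000
1785,1.587891
1790,1.540625
1795,1.510547
1800,1.500000
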