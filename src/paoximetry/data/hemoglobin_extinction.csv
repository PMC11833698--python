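# Molar extinction of human oxy- and deoxyhemoglobin, 650-1800 nm.
# Compiled approximation: NIR-I region follows the standard tabulated
# compilation; NIR-II extension follows published whole-blood
# absorption spectra.  mu_a [cm^-1] = ln(10) * eps * C[mol/L].
# provenance: paoximetry compiled table v1 (PCHIP-densified anchors,
# see scripts/make_extinction_tables.py)
wavelength_nm,eps_HbO2_cm1M1,eps_Hb_cm1M1
650,368.0000,3750.0000
655,339.6587,3476.6576
660,320.0000,3227.0000
665,309.8392,3003.2243
670,302.5395,2794.8950
675,296.4699,2597.6182
680,290.0000,2407.0000
685,281.1966,2219.6648
690,276.0000,2052.0000
695,280.7895,1910.1444
700,290.0000,1794.0000
705,301.4833,1711.0328
710,314.0000,1636.0000
715,323.0431,1546.6116
720,334.0000,1465.0000
725,358.6842,1401.9451
730,390.0000,1356.0000
735,417.1250,1324.9129
740,446.0000,1310.0000
745,481.1321,1343.2300
750,518.0000,1405.0000
755,552.5004,1490.7700
760,586.0000,1548.0000
765,618.5005,1503.8817
770,650.0000,1420.0000
775,680.9238,1321.3683
780,710.0000,1210.0000
785,735.2144,1098.8235
790,760.0000,1000.0000
795,788.1422,919.9914
800,816.0000,870.0000
805,840.2215,855.3351
810,864.0000,846.0000
815,889.6850,837.5424
820,916.0000,830.0000
825,943.3588,821.6451
830,971.5702,812.9901
835,998.4965,805.3400
840,1022.0000,800.0000
845,1041.7124,796.9531
850,1059.3201,794.7917
855,1075.7678,792.7344
860,1092.0000,790.0000
865,1108.5219,785.9375
870,1124.7857,780.8333
875,1140.1567,775.3125
880,1154.0000,770.0000
885,1166.3151,765.1875
890,1177.6391,760.5000
895,1188.1435,755.5625
900,1198.0000,750.0000
905,1208.7067,743.0625
910,1219.7949,735.0000
915,1228.4856,726.9375
920,1232.0000,720.0000
925,1230.0809,714.3232
930,1225.3824,709.1951
935,1219.4926,704.4695
940,1214.0000,700.0000
945,1209.2672,695.3024
950,1204.0000,692.0000
955,1197.8556,690.8744
960,1190.0000,690.0000
965,1178.1884,688.8357
970,1162.5917,687.5762
975,1145.1992,686.2786
980,1128.0000,685.0000
985,1109.9266,683.9323
990,1090.4103,682.9861
995,1072.1889,681.7969
1000,1058.0000,680.0000
1005,1047.8722,672.0576
1010,1039.5376,654.8805
1015,1032.2898,631.7776
1020,1025.4220,606.0574
1025,1018.2276,581.0286
1030,1010.0000,560.0000
1035,1000.9109,541.3578
1040,991.5451,521.9541
1045,981.8160,502.7962
1050,971.6366,484.8916
1055,960.9201,469.2474
1060,949.5798,456.8712
1065,937.5180,448.6721
1070,924.3630,442.2245
1075,910.1213,436.2387
1080,895.0041,430.9080
1085,879.2223,426.4256
1090,862.9869,422.9846
1095,846.5092,420.7784
1100,830.0000,420.0000
1105,813.2056,420.1225
1110,795.8137,420.4800
1115,777.9479,421.0575
1120,759.7318,421.8400
1125,741.2890,422.8125
1130,722.7431,423.9600
1135,704.2177,425.2675
1140,685.8363,426.7200
1145,667.7225,428.3025
1150,650.0000,430.0000
1155,632.4082,432.6877
1160,614.6730,437.0674
1165,596.8975,442.8640
1170,579.1847,449.8023
1175,561.6379,457.6072
1180,544.3600,466.0035
1185,527.4541,474.7161
1190,511.0235,483.4698
1195,495.1711,491.9895
1200,480.0000,500.0000
1205,465.3714,507.9334
1210,451.1387,516.2791
1215,437.3936,524.8478
1220,424.2276,533.4504
1225,411.7326,541.8975
1230,400.0000,550.0000
1235,388.8404,558.0900
1240,378.2285,566.2063
1245,368.5024,573.7194
1250,360.0000,580.0000
1255,352.3800,585.2296
1260,345.0844,590.0447
1265,338.1267,594.4982
1270,331.5200,598.6431
1275,325.2778,602.5325
1280,319.4133,606.2192
1285,313.9400,609.7564
1290,308.8711,613.1969
1295,304.2200,616.5938
1300,300.0000,620.0000
1305,296.1360,623.3471
1310,292.5280,626.5486
1315,289.1520,629.6300
1320,285.9840,632.6171
1325,283.0000,635.5357
1330,280.1760,638.4114
1335,277.4880,641.2700
1340,274.9120,644.1371
1345,272.4240,647.0386
1350,270.0000,650.0000
1355,267.6206,653.1271
1360,265.2911,656.4518
1365,263.0243,659.8894
1370,260.8332,663.3553
1375,258.7308,666.7647
1380,256.7298,670.0329
1385,254.8434,673.0753
1390,253.0843,675.8071
1395,251.4655,678.1435
1400,250.0000,680.0000
1405,248.6371,681.5784
1410,247.3169,683.1329
1415,246.0388,684.6575
1420,244.8021,686.1459
1425,243.6058,687.5919
1430,242.4492,688.9894
1435,241.3317,690.3322
1440,240.2523,691.6141
1445,239.2104,692.8290
1450,238.2051,693.9706
1455,237.2358,695.0328
1460,236.3015,696.0094
1465,235.4017,696.8943
1470,234.5354,697.6812
1475,233.7019,698.3640
1480,232.9005,698.9365
1485,232.1304,699.3925
1490,231.3908,699.7259
1495,230.6809,699.9304
1500,230.0000,700.0000
1505,229.3417,700.0000
1510,228.7000,700.0000
1515,228.0750,700.0000
1520,227.4667,700.0000
1525,226.8750,700.0000
1530,226.3000,700.0000
1535,225.7417,700.0000
1540,225.2000,700.0000
1545,224.6750,700.0000
1550,224.1667,700.0000
1555,223.6750,700.0000
1560,223.2000,700.0000
1565,222.7417,700.0000
1570,222.3000,700.0000
1575,221.8750,700.0000
1580,221.4667,700.0000
1585,221.0750,700.0000
1590,220.7000,700.0000
1595,220.3417,700.0000
1600,220.0000,700.0000
1605,219.6748,699.9513
1610,219.3650,699.8100
1615,219.0694,699.5838
1620,218.7867,699.2800
1625,218.5156,698.9062
1630,218.2550,698.4700
1635,218.0035,697.9787
1640,217.7600,697.4400
1645,217.5231,696.8613
1650,217.2917,696.2500
1655,217.0644,695.6138
1660,216.8400,694.9600
1665,216.6173,694.2962
1670,216.3950,693.6300
1675,216.1719,692.9688
1680,215.9467,692.3200
1685,215.7181,691.6912
1690,215.4850,691.0900
1695,215.2460,690.5238
1700,215.0000,690.0000
1705,214.7500,689.5000
1710,214.5000,689.0000
1715,214.2500,688.5000
1720,214.0000,688.0000
1725,213.7500,687.5000
1730,213.5000,687.0000
1735,213.2500,686.5000
1740,213.0000,686.0000
1745,212.7500,685.5000
1750,212.5000,685.0000
1755,212.2500,684.5000
1760,212.0000,684.0000
1765,211.7500,683.5000
1770,211.5000,683.0000
1775,211.2500,682.5000
1780,211.0000,682.0000
1785,210.7500,681.5000
1790,210.5000,681.0000
1795,210.2500,680.5000
1800,210.0000,680.0000
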