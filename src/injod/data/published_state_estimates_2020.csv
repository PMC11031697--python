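state,population,overdose_deaths,status,deaths,deaths_lo,deaths_hi,pct,pct_lo,pct_hi,rate,rate_lo,rate_hi
Alabama,3834249,1023,ok,456,407,513,44.6,39.7,50.1,11.89,10.61,13.37
Alaska,552427,158,ok,83,68,100,52.6,42.8,63.3,15.06,12.25,18.11
Arizona,5774978,2483,ok,779,539,1249,31.4,21.7,50.3,13.49,9.33,21.63
Arkansas,2330808,540,ok,248,192,299,46,35.5,55.4,10.66,8.23,12.85
California,30576844,8778,ok,3475,3343,3620,39.6,38.1,41.2,11.37,10.93,11.84
Colorado,4557684,1461,ok,553,513,599,37.9,35.1,41,12.14,11.26,13.14
Connecticut,2838054,1364,ok,543,510,578,39.8,37.4,42.4,19.13,17.99,20.36
Delaware,782153,444,ok,175,159,192,39.3,35.8,43.3,22.33,20.31,24.59
District of Columbia,583228,421,suppressed,,,,,,,,,
Florida,17482580,7202,ok,3767,3475,4073,52.3,48.3,56.6,21.54,19.88,23.30
Georgia,8210067,1902,ok,773,683,868,40.7,35.9,45.7,9.42,8.32,10.58
Hawaii,1111188,273,suppressed,,,,,,,,,
Idaho,1375870,284,nonreporting,,,,,,,,,
Illinois,9809562,3532,ok,1063,971,1169,30.1,27.5,33.1,10.84,9.90,11.92
Indiana,5188514,2305,ok,1250,1161,1344,54.2,50.4,58.3,24.10,22.38,25.90
Iowa,2438002,428,ok,171,150,194,40,35,45.3,7.01,6.14,7.95
Kansas,2217059,474,ok,222,178,265,46.8,37.5,55.8,10.01,8.03,11.94
Kentucky,3475334,2075,ok,1104,1025,1185,53.2,49.4,57.1,31.77,29.50,34.09
Louisiana,3564038,1889,ok,847,718,986,44.8,38,52.2,23.76,20.16,27.67
Maine,1101973,495,ok,229,202,257,46.3,40.8,52,20.80,18.34,23.34
Maryland,4721883,2757,nonreporting,,,,,,,,,
Massachusetts,5552051,2298,ok,1375,1335,1416,59.8,58.1,61.6,24.77,24.05,25.51
Michigan,7839742,2742,ok,1295,1237,1355,47.2,45.1,49.4,16.52,15.78,17.29
Minnesota,4356123,1035,ok,413,379,450,39.9,36.6,43.5,9.47,8.69,10.33
Mississippi,2273653,582,ok,256,202,318,44.1,34.7,54.6,11.28,8.89,13.99
Missouri,4780119,1859,ok,921,856,987,49.5,46.1,53.1,19.26,17.92,20.64
Montana,850894,160,suppressed,,,,,,,,,
Nebraska,1462537,209,ok,94,69,115,45,33.2,55.2,6.44,4.74,7.88
Nevada,2440679,817,ok,292,185,440,35.7,22.6,53.8,11.95,7.58,18.01
New Hampshire,1113141,391,suppressed,,,,,,,,,
New Jersey,6947836,2827,ok,1175,1130,1223,41.6,40,43.3,16.91,16.26,17.60
New Mexico,1633828,778,nonreporting,,,,,,,,,
New York,15348422,4950,ok,2082,2025,2142,42.1,40.9,43.3,13.57,13.20,13.95
North Carolina,8294423,3129,ok,1529,1411,1654,48.9,45.1,52.9,18.44,17.01,19.94
North Dakota,583680,110,suppressed,,,,,,,,,
Ohio,9124576,5179,ok,2688,2485,2903,51.9,48,56,29.46,27.23,31.81
Oklahoma,3027263,750,ok,289,245,336,38.5,32.7,44.7,9.55,8.09,11.09
Oregon,3380729,794,nonreporting,,,,,,,,,
Pennsylvania,10162497,5141,ok,2877,2684,3077,56,52.2,59.8,28.31,26.41,30.27
Rhode Island,855276,395,ok,182,162,203,46,41,51.4,21.24,18.95,23.73
South Carolina,4100115,1730,ok,487,392,607,28.2,22.7,35.1,11.89,9.57,14.79
South Dakota,674238,81,ok,37,26,49,45.4,32,59.9,5.45,3.84,7.20
Tennessee,5373433,3021,ok,1587,1446,1734,52.5,47.9,57.4,29.53,26.91,32.27
Texas,21925627,4116,ok,1677,1548,1823,40.7,37.6,44.3,7.65,7.06,8.32
Utah,2320603,619,ok,217,193,250,35.1,31.1,40.4,9.36,8.30,10.77
Vermont,510181,189,ok,93,82,104,49.4,43.6,55.2,18.29,16.14,20.44
Virginia,6724143,2226,ok,990,888,1101,44.5,39.9,49.5,14.72,13.21,16.38
Washington,6027818,1705,nonreporting,,,,,,,,,
West Virginia,1428520,1328,suppressed,,,,,,,,,
Wisconsin,4574131,1523,ok,771,694,857,50.6,45.6,56.3,16.86,15.18,18.74
Wyoming,449237,99,suppressed,,,,,,,,,
National,256662010,91071,national,38253,34839,42181,45.1,41.1,49.8,15.97,14.55,17.61
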