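respondent_id,he_item_1,he_item_2,he_item_3,he_item_4,he_total,age,gender,married,education_years,residence_rural,insurance,health_status,monthly_income_group,annual_income_group,age_sq,consumption,city_id,community_id,consumption_item_1,consumption_item_2,consumption_item_3,consumption_item_4,consumption_item_5,weight
1,3,0,3,2,8,39.78096781175755,0.0,1.0,12.0,0.0,1.0,4.0,2.0,4.0,1582.52540004009,1.0,1.0,5.0,1.0,0.75,0.75,1.0,1.0,1.0
2,5,5,6,5,21,39.55673402363417,1.0,0.0,16.0,1.0,0.0,4.0,2.0,3.0,1564.7352066165372,0.12140867675732162,1.0,3.0,0.5,0.25,0.0,0.0,0.0,1.0
3,1,2,1,2,6,24.295756671070833,0.0,0.0,12.0,1.0,1.0,3.0,4.0,6.0,590.2837922198829,0.8286100270010802,1.0,5.0,0.5,0.75,1.0,1.0,0.5,1.0
4,1,0,0,2,3,35.27279976806265,1.0,0.0,16.0,0.0,0.0,4.0,3.0,6.0,1244.1704034778404,0.7554907318962835,4.0,14.0,0.5,1.0,0.75,0.5,0.75,1.0
5,0,2,1,0,3,26.380736222144762,0.0,0.0,0.0,1.0,0.0,4.0,2.0,2.0,695.9432436223807,0.0,2.0,6.0,0.0,0.0,0.0,0.0,0.25,1.0
6,3,3,1,4,11,26.44046759016917,0.0,1.0,9.0,1.0,0.0,3.0,1.0,3.0,699.0983263867863,0.06618380998526682,2.0,6.0,0.0,0.0,0.25,0.25,0.0,1.0
7,3,2,4,3,12,33.50479854150155,0.0,1.0,6.0,1.0,0.0,4.0,2.0,6.0,1122.5715253066044,0.5284059955286949,4.0,14.0,1.0,0.25,0.75,0.25,0.25,1.0
8,3,1,1,2,7,50.79350348562458,0.0,1.0,6.0,0.0,1.0,4.0,3.0,2.0,2579.979996344157,0.4148469154521834,3.0,10.0,0.5,0.0,0.5,0.5,0.5,1.0
9,7,6,8,7,28,27.497157441399743,1.0,0.0,6.0,0.0,1.0,2.0,1.0,4.0,756.0936673571252,0.3642931917839504,4.0,12.0,0.25,0.25,0.0,0.75,0.5,1.0
10,0,1,0,0,1,43.63163724485989,0.0,0.0,6.0,0.0,1.0,3.0,1.0,3.0,1903.7197686670445,0.17040675439305317,4.0,14.0,0.25,0.0,0.25,0.0,0.5,1.0
11,5,4,5,4,18,22.911020251179558,1.0,0.0,16.0,0.0,1.0,3.0,1.0,5.0,524.9148489499598,0.5179860559566831,0.0,0.0,0.25,0.75,0.5,0.25,0.75,1.0
12,8,8,7,8,31,34.67203753819273,1.0,0.0,6.0,0.0,1.0,4.0,1.0,2.0,1202.150187049846,0.8763584594798043,1.0,3.0,0.75,0.75,0.75,0.75,1.0,1.0
13,2,1,0,1,4,37.79613900906685,0.0,1.0,9.0,1.0,1.0,4.0,2.0,1.0,1428.5481239927049,0.2977362194112042,3.0,11.0,0.5,0.5,0.0,0.25,0.25,1.0
14,3,2,1,3,9,45.25904488662199,0.0,0.0,9.0,0.0,1.0,3.0,4.0,1.0,2048.3811440492645,0.9328329714088665,4.0,12.0,0.75,0.75,1.0,0.75,1.0,1.0
15,1,0,1,4,6,44.692004866918396,1.0,1.0,9.0,1.0,1.0,3.0,2.0,2.0,1997.3752990246576,0.8273603818440728,0.0,1.0,1.0,1.0,0.5,0.75,0.5,1.0
16,1,0,2,1,4,41.76752065058523,0.0,0.0,12.0,1.0,0.0,5.0,2.0,2.0,1744.525781297064,0.1194798683373408,1.0,5.0,0.25,0.5,0.0,0.0,0.0,1.0
17,4,2,2,2,10,33.420489150150964,1.0,1.0,12.0,0.0,0.0,3.0,4.0,3.0,1116.9290950353584,0.5264771871087142,2.0,7.0,0.75,0.5,0.75,0.25,0.25,1.0
18,6,8,7,7,28,28.850346440218804,1.0,1.0,16.0,1.0,0.0,2.0,4.0,6.0,832.3424897206457,0.12079862053893443,3.0,10.0,0.0,0.0,0.25,0.25,0.25,1.0
19,8,8,8,8,32,47.436160735459,1.0,1.0,9.0,0.0,1.0,4.0,3.0,6.0,2250.189345320302,0.9384497043268027,0.0,1.0,1.0,1.0,0.75,0.75,0.75,1.0
20,2,3,2,2,9,33.86317143932688,0.0,1.0,6.0,0.0,0.0,4.0,4.0,2.0,1146.7143799292435,0.5779450223382274,3.0,9.0,1.0,0.5,1.0,0.0,0.25,1.0
21,8,8,8,8,32,23.75849632975209,0.0,0.0,9.0,0.0,1.0,3.0,3.0,4.0,564.4661478508436,0.36337908022267007,1.0,4.0,0.25,0.0,0.25,0.75,0.5,1.0
22,1,2,3,5,11,23.819401266627885,1.0,1.0,9.0,1.0,0.0,5.0,1.0,2.0,567.3638767006341,0.2328020545829447,1.0,5.0,0.0,0.25,0.25,0.25,0.5,1.0
23,8,8,8,8,32,30.098512854303276,1.0,0.0,12.0,0.0,1.0,5.0,2.0,4.0,905.9204760406595,0.8856945951485294,2.0,6.0,1.0,1.0,1.0,0.75,0.25,1.0
24,1,4,2,1,8,40.65835638892839,1.0,0.0,6.0,1.0,1.0,4.0,1.0,4.0,1653.101944249114,0.17788318868638386,2.0,8.0,0.5,0.25,0.25,0.0,0.0,1.0
25,4,1,3,4,12,36.21072292577641,1.0,0.0,9.0,1.0,1.0,4.0,1.0,4.0,1311.2164548073492,0.4797119732358566,3.0,10.0,0.75,0.5,0.5,0.5,0.0,1.0
26,4,3,2,2,11,42.12859192561755,1.0,1.0,9.0,1.0,1.0,5.0,2.0,2.0,1774.818257635208,0.3536697821664654,1.0,4.0,0.25,0.0,0.25,0.5,0.75,1.0
27,8,8,8,8,32,33.07843218165132,1.0,1.0,19.0,0.0,0.0,3.0,4.0,6.0,1094.1826755961058,0.9462993010076127,4.0,12.0,1.0,1.0,0.5,1.0,0.75,1.0
28,6,4,5,5,20,38.59178981173455,0.0,1.0,19.0,0.0,0.0,1.0,4.0,2.0,1489.3262408730986,0.9356067843455416,0.0,1.0,0.75,1.0,1.0,0.75,0.75,1.0
29,3,0,2,1,6,43.6275685067719,0.0,1.0,6.0,1.0,0.0,5.0,1.0,4.0,1903.3647338130754,0.5421763804703343,4.0,12.0,0.75,0.5,0.25,0.75,0.25,1.0
30,6,4,5,7,22,33.98336860420039,0.0,1.0,9.0,0.0,0.0,3.0,3.0,6.0,1154.869341688953,0.5380838153320658,0.0,0.0,1.0,0.75,0.0,0.5,0.25,1.0
31,2,1,3,2,8,46.80069924240355,0.0,1.0,6.0,0.0,1.0,4.0,2.0,6.0,2190.3054495779124,0.9990858884387195,3.0,11.0,1.0,0.5,1.0,1.0,1.0,1.0
32,3,2,1,2,8,28.38815346285916,0.0,1.0,6.0,0.0,1.0,5.0,3.0,6.0,805.8872570308426,0.35454626493599334,1.0,3.0,0.0,0.0,1.0,0.5,0.25,1.0
33,6,5,6,2,19,30.935681117428636,1.0,0.0,9.0,1.0,0.0,1.0,2.0,3.0,957.0163661992307,0.42076770371301264,1.0,4.0,0.25,0.25,0.25,0.75,0.5,1.0
34,5,2,0,3,10,29.975222306222985,0.0,1.0,16.0,1.0,0.0,2.0,1.0,4.0,898.513952307488,0.05931743191032332,0.0,1.0,0.25,0.0,0.0,0.0,0.25,1.0
35,4,3,4,5,16,26.11436973519544,0.0,1.0,9.0,0.0,0.0,2.0,4.0,4.0,681.9603066664915,0.6961732999859602,3.0,9.0,0.25,1.0,0.75,0.5,0.75,1.0
36,3,1,2,5,11,44.21083021557544,0.0,1.0,9.0,0.0,0.0,3.0,2.0,4.0,1954.5975083504384,0.9930645148804702,0.0,0.0,1.0,1.0,0.75,0.75,1.0,1.0
37,2,3,5,4,14,30.948848299265713,1.0,1.0,0.0,1.0,0.0,4.0,2.0,2.0,957.8312110509622,0.4744684027053999,3.0,10.0,0.25,0.0,0.5,0.75,0.75,1.0
38,3,2,5,5,15,33.76380387693076,1.0,0.0,9.0,1.0,0.0,4.0,1.0,4.0,1139.9944522398446,0.3662220002039312,3.0,10.0,0.5,0.0,0.0,0.75,0.5,1.0
39,0,0,0,2,2,38.59611014823557,1.0,0.0,6.0,0.0,1.0,3.0,1.0,1.0,1489.6597185747326,0.05924832486573706,4.0,14.0,0.0,0.25,0.25,0.0,0.0,1.0
40,5,4,3,4,16,42.415445676268,1.0,1.0,9.0,0.0,1.0,2.0,3.0,5.0,1799.0700319164418,0.5916463002352806,3.0,11.0,0.5,1.0,0.75,0.5,0.0,1.0
41,0,2,1,1,4,44.99693163823873,1.0,1.0,6.0,0.0,0.0,1.0,3.0,6.0,2024.7238568563293,0.5873859483106906,1.0,3.0,0.25,0.5,0.25,0.75,1.0,1.0
42,1,1,2,1,5,36.43420574666252,0.0,1.0,9.0,0.0,1.0,4.0,3.0,5.0,1327.4513483901362,0.8735155394985431,3.0,9.0,0.5,0.75,1.0,0.75,1.0,1.0
43,3,3,4,2,12,29.961303183052802,0.0,0.0,0.0,1.0,0.0,3.0,3.0,2.0,897.67968842681,0.47494024483461467,4.0,12.0,0.25,0.75,0.75,0.5,0.0,1.0
44,4,3,1,2,10,35.765687283304366,1.0,1.0,6.0,0.0,1.0,4.0,4.0,5.0,1279.1843868471196,0.23344358905416568,1.0,4.0,0.5,0.0,0.75,0.0,0.0,1.0
45,3,2,2,2,9,21.584582732128187,0.0,0.0,19.0,0.0,1.0,4.0,2.0,3.0,465.8942117200863,0.40791143033265365,0.0,0.0,0.5,0.25,0.5,0.25,0.5,1.0
46,8,7,3,6,24,23.308150539250818,0.0,0.0,6.0,0.0,0.0,4.0,1.0,5.0,543.2698815603782,0.5199148643766639,4.0,12.0,0.5,0.5,0.5,0.25,0.75,1.0
47,3,1,1,0,5,25.630340148740153,0.0,1.0,6.0,0.0,0.0,4.0,4.0,1.0,656.9143361401215,0.8041847541891218,0.0,2.0,0.75,0.75,1.0,0.25,1.0,1.0
48,2,2,1,5,10,26.910565044350253,0.0,0.0,19.0,0.0,1.0,4.0,2.0,3.0,724.1785110062058,0.4050370320985586,2.0,8.0,0.25,0.75,0.0,0.25,0.75,1.0
49,2,1,2,2,7,42.00338721081029,1.0,1.0,19.0,0.0,0.0,4.0,4.0,1.0,1764.2845371812614,0.8167369722265877,1.0,5.0,1.0,0.75,0.75,0.5,0.75,1.0
50,4,3,2,3,12,27.347390835440464,1.0,1.0,6.0,1.0,1.0,3.0,3.0,1.0,747.8797855063331,0.41954953680883905,0.0,0.0,0.75,0.0,0.5,0.5,0.25,1.0
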