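age_years,sex,median_weight_kg
0,male,3.3
0.0833,male,4.5
0.1667,male,5.6
0.25,male,6.4
0.3333,male,7.0
0.4167,male,7.5
0.5,male,7.9
0.75,male,8.9
1,male,9.6
1.5,male,10.9
2,male,12.2
3,male,14.3
4,male,16.3
5,male,18.3
6,male,20.5
7,male,22.9
8,male,25.4
9,male,28.1
10,male,31.2
11,male,35.3
12,male,39.8
13,male,45.3
14,male,50.8
15,male,56.0
16,male,60.8
17,male,64.4
18,male,66.9
0,female,3.2
0.0833,female,4.2
0.1667,female,5.1
0.25,female,5.8
0.3333,female,6.4
0.4167,female,6.9
0.5,female,7.3
0.75,female,8.2
1,female,8.9
1.5,female,10.2
2,female,11.5
3,female,13.9
4,female,16.1
5,female,18.2
6,female,20.2
7,female,22.4
8,female,25.0
9,female,28.2
10,female,31.9
11,female,36.9
12,female,41.5
13,female,45.8
14,female,49.4
15,female,51.9
16,female,53.9
17,female,55.0
18,female,56.3
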