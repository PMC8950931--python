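age_months,median_weight_kg
0,3.3
1,4.3
2,5.4
3,6.1
6,7.6
9,8.6
12,9.3
18,10.6
24,11.9
36,14.1
48,16.2
60,18.3
72,20.4
84,22.7
96,25.2
108,28.2
120,31.6
132,35.8
144,40.5
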