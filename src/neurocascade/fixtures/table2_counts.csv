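time_days,n,total_mean,total_sem,apop_mean,apop_sem
0.0833333333333333,3,2690,320,0,0
0.5,2,4157,784,0,0
1,4,5392,557,40,18
2,5,5803,138,121,33
3,3,4781,344,48,25
4,5,4186,201,23,14
8,6,3518,307,10,11
11,3,2427,202,0,0
15,4,1342,185,33,13
18,3,1233,302,0,0
22,4,752,53,0,0
32,3,950,234,13,16
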