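time_days,n_exp1,nsc_mean,nsc_sem,anp_mean,anp_sem,n_exp2,nb_mean,nb_sem,gc_mean,gc_sem
0.0833333333333333,4,11.16,2.14,85.07,3.62,,,,,
1,4,5.68,0.57,60.14,2.59,3,51.94,7.25,0.2,0.24
2,5,3.29,0.79,42.31,4.81,2,76.42,3.24,0.32,0.46
4,5,2.53,0.69,20.37,0.85,3,95.06,1.12,1.52,0.51
8,5,0,0,4.87,1.38,3,96.24,0.76,2.48,0.31
15,,,,,,2,86.61,1.26,4.72,0.05
32,,,,,,3,14.86,3.62,77.34,6.81
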