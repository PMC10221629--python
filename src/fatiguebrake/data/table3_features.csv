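subject,session,cf_ch7,cf_ch10,pse_ch7,pse_ch10
1,1,6.7,7.1,0.72,0.68
1,5,7.2,7.4,0.86,0.79
2,1,6.5,6.8,0.78,0.71
2,5,7.9,7.5,0.89,0.77
3,1,6.1,5.8,0.62,0.58
3,5,7.3,5.9,0.67,0.72
4,1,7.8,7.3,0.81,0.77
4,5,6.8,7.2,0.73,0.76
5,1,6.2,6.9,0.65,0.62
5,5,7.6,7.5,0.79,0.78
6,1,7.1,7.1,0.75,0.72
6,5,7.6,7.5,0.86,0.93
7,1,5.6,6.8,0.61,0.61
7,5,7.3,7.3,0.82,0.73
8,1,6.8,7.2,0.77,0.69
8,5,8,7.4,0.83,0.75
9,1,7.1,7.3,0.73,0.76
9,5,7.8,8.2,0.81,0.88
10,1,6.5,7.5,0.7,0.81
10,5,8.6,7.8,0.95,0.84
11,1,7.2,7,0.86,0.69
11,5,7.7,7.7,0.75,0.83
12,1,6.7,7.4,0.72,0.78
12,5,8.7,7.1,0.72,0.88
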