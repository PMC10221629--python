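subject,session,congruent_ms,incongruent_ms,stroop_effect_ms,fss,excluded
1,1,790,1118,328,0.5,0
1,5,856,1042,186,1.5,0
2,1,978,1245,267,0,0
2,5,655,923,268,2,0
3,1,921,1154,233,0,0
3,5,1062,1229,167,1,0
4,1,958,898,-60,0.5,0
4,5,894,830,-64,0.5,1
5,1,898,1100,202,0.5,0
5,5,1235,1449,214,2,0
6,1,729,999,270,1,0
6,5,1098,1378,280,2.5,0
7,1,872,1023,151,0,0
7,5,1036,1330,294,1.5,0
8,1,837,1025,188,0.5,0
8,5,1267,1543,276,2.5,0
9,1,945,1201,256,1,0
9,5,963,1124,161,1.5,0
10,1,991,1042,51,0.5,0
10,5,731,1079,348,3,0
11,1,936,1071,135,0,0
11,5,1022,1215,193,1.5,0
12,1,720,1011,291,0.5,0
12,5,858,1173,315,2.5,0
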