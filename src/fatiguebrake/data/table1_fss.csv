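score,description
0,No fatigue or fatigue within the usual range experienced by the individual
1,Slightly or briefly above the individual's typical fatigue level
2,"Noticeable fatigue, requiring some effort to cope with"
3,"Significant fatigue, affecting daily activities and work performance"
4,"Extreme fatigue, rendering the individual incapable of performing normal daily activities and work, necessitating immediate rest and recovery"
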