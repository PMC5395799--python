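class,min_minutes,max_minutes
1,0,15
2,15,30
3,30,60
4,60,90
5,90,120
6,120,999999
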