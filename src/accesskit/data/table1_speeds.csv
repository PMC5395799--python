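id,cover_class,kmh
1,Forest,1
2,Grass,2
3,Bare rocky,3
4,Scrub,0.75
101,Stream class 1,2
102,Stream class 2,2
103,Stream class 3,2
104,Stream class 4,2
105,Stream class 5,0
201,National road/Hi-way,50
202,Provincial road,25
203,Local road/track,10
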