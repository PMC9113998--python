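category,speed
1,1.50
2,1.50
3,3.00
4,3.00
5,NA
6,3.00
7,1.15
8,1.50
10,NA
200,NA
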