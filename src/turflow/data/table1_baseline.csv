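case,0
1,0.18
2,0.12
3,0.24
4,0.25
5,0.99
6,0.04
7,0.04
8,0.11
9,0.09
10,2.38
11,0.07
12,0.02
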