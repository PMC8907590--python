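case,1,3,5,7,9,11,13,15,17,19
1,3.42,4.12,2.85,2.25,1.11,0.62,0.14,0.19,0.25,0.30
2,1.94,1.03,3.97,4.63,1.19,0.74,0.13,0.11,0.09,0.15
3,2.49,2.16,1.45,1.94,1.35,1.17,1.56,2.52,1.24,0.33
4,14.09,9.52,12.11,18.96,13.45,0.28,0.06,2.07,0.50,0.05
5,1.43,0.23,3.54,7.62,9.91,4.11,6.36,6.20,2.10,0.20
6,0.87,2.31,3.69,3.46,4.89,7.11,3.12,3.89,4.65,2.22
7,8.95,15.11,19.85,24.81,19.61,10.83,3.52,0.36,3.52,3.59
8,2.62,2.00,6.33,1.34,1.18,0.64,0.67,2.60,0.86,1.70
9,1.77,0.28,7.36,10.60,0.40,1.88,0.62,0.35,0.09,0.52
10,8.20,17.56,7.33,8.33,3.32,0.14,0.12,0.08,0.06,0.06
11,0.21,4.47,1.70,25.49,2.64,2.07,0.26,0.17,0.12,0.08
12,4.03,3.61,1.63,14.75,18.63,5.64,1.88,1.19,1.09,0.14
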