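case,excluded,exclusion_reason,1,3,5,7,9,11,13,15,17,19
1,0,,4.19,2.34,2.58,5.83,16.95,12.30,9.66,3.21,2.15,0.91
2,1,post-stenotic segment spasm,1.49,0.05,0.03,0.03,0.01,0.01,0.02,0.01,0.02,0.03
3,0,,0.55,4.25,18.26,20.16,13.84,4.26,4.73,2.73,9.07,2.46
4,0,,17.08,19.59,34.29,55.76,59.48,61.97,48.49,19.83,39.47,21.31
5,0,,9.08,20.33,32.39,35.09,58.24,66.02,62.10,54.93,38.95,10.44
6,0,,9.94,31.85,41.67,42.24,20.57,2.84,2.31,2.00,4.01,6.96
7,0,,4.26,17.60,17.76,26.51,53.19,23.31,7.66,0.08,0.12,0.09
8,0,,7.25,24.21,56.23,67.26,56.19,39.24,39.53,32.59,23.11,1.40
9,0,,2.73,5.68,8.60,38.97,43.89,44.08,37.16,24.57,10.38,3.78
10,0,,2.05,6.64,32.13,19.62,24.54,9.41,5.99,7.35,3.09,0.61
11,0,,1.76,2.86,5.09,5.67,41.42,13.89,2.38,27.19,1.13,0.87
12,0,,0.31,0.33,3.74,16.68,13.43,21.15,9.26,4.02,5.32,3.32
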