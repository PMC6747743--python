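participant_id,hispanic,sri,tst,waketime,bedtime
1,1,62.76,5.96,8.04,1.85
2,0,85.04,4.87,8.14,3.06
3,1,77.11,8.11,9.48,24.77
4,1,84.53,7.98,9.91,1.79
5,0,63.93,8.47,9.4,24.76
6,0,80.09,6.48,7.84,1.08
7,0,80.91,7.79,8.99,24.95
8,1,53.43,6.11,7.94,1.63
9,0,75.77,6.58,8.36,1.45
10,0,70.04,7.88,8.97,24.61
11,0,71.4,5.68,9.13,3.05
12,0,79.91,7.99,9.84,1.54
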