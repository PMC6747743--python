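participant_id,chron_t1,chron_t2,horvath_t1,horvath_t2,grimage_t1,grimage_t2
1,18.87,19.06,20.89,23.20,20.46,22.28
2,18.67,18.87,21.79,22.70,21.35,22.24
3,18.62,18.81,26.29,18.26,26.51,17.99
4,18.61,18.81,17.43,14.61,17.41,15.43
5,18.26,18.46,21.99,19.48,22.54,19.70
6,19.84,20.04,20.62,16.03,20.84,16.81
7,19.03,19.23,24.71,19.75,25.22,20.11
8,18.86,19.05,15.79,18.81,16.41,19.56
9,18.85,19.05,18.52,22.35,18.69,22.05
10,18.44,18.64,16.51,19.11,16.79,19.27
11,18.35,18.55,24.04,25.93,23.55,25.50
12,18.18,18.37,20.89,21.24,21.14,21.57
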