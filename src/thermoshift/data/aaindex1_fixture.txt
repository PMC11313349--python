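H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      1.8     -4.5     -3.5     -3.5      2.5     -3.5     -3.5     -0.4     -3.2      4.5
      3.8     -3.9      1.9      2.8     -1.6     -0.8     -0.7     -0.9     -1.3      4.2
//
H HOPT810101
D Hydrophilicity value (Hopp-Woods, 1981)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     -0.5        3      0.2        3       -1      0.2        3        0     -0.5     -1.8
     -1.8        3     -1.3     -2.5        0      0.3     -0.4     -3.4     -2.3     -1.5
//
H GRAR740102
D Polarity (Grantham, 1974)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      8.1     10.5     11.6       13      5.5     10.5     12.3        9     10.4      5.2
      4.9     11.3      5.7      5.2        8      9.2      8.6      5.4      6.2      5.9
//
H ZIMJ680102
D Bulkiness (Zimmerman et al., 1968)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     11.5    14.28    12.82    11.68    13.46    14.45    13.57      3.4    13.69     21.4
     21.4    15.71    16.25     19.8    17.43     9.47    15.77    21.67    18.03    21.57
//
H CHOP780201
D Normalized frequency of alpha-helix (Chou-Fasman, 1978)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.42     0.98     0.67     1.01      0.7     1.11     1.51     0.57        1     1.08
     1.21     1.16     1.45     1.13     0.57     0.77     0.83     1.08     0.69     1.06
//
H SYN1000001
D Synthetic test entry with a missing value
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      8.1     10.5     11.6       13      5.5     10.5     12.3        9     10.4      5.2
      4.9     11.3      5.7      5.2        8      9.2      8.6       NA      6.2      5.9
//
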