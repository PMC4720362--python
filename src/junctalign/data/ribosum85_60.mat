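# RIBOSUM85-60 substitution scores for RNA structural alignment.
# Transcribed from the RSEARCH distribution (Klein RJ, Eddy SR,
# BMC Bioinformatics 2003, 4:44): a 4x4 block for unpaired bases and a
# 16x16 block for base pairs, in bits (log2 odds).  Only the upper
# triangle of each block is stored; the loader symmetrizes.
SINGLE
     A      C      G      U
A   2.22  -1.86  -1.46  -1.39
C          1.16  -2.48  -1.05
G                 1.03  -1.74
U                        1.65
PAIR
      AA     AC     AG     AU     CA     CC     CG     CU     GA     GC     GG     GU     UA     UC     UG     UU
AA  -2.49  -7.04  -8.24  -4.32  -8.84 -14.37  -4.68 -12.64  -6.86  -5.03  -8.39  -5.84  -4.01 -11.32  -6.16  -9.05
AC         -2.11  -8.89  -2.04  -9.37  -9.08  -5.86 -10.45  -9.73  -3.81 -11.05  -4.72  -5.33  -8.67  -6.93  -7.83
AG                -0.80  -5.13 -10.37 -14.53  -4.57 -10.14  -8.61  -5.77  -5.38  -6.60  -5.43  -8.87  -5.94 -11.07
AU                        4.49  -5.56  -6.71   1.67  -5.17  -5.33   2.70  -5.61   0.59   1.61  -4.81  -0.51  -2.98
CA                               -5.13 -10.44  -3.57  -8.49  -7.98  -5.95 -11.36  -7.93  -2.42  -7.08  -5.63  -8.39
CC                                      -3.59  -5.71  -5.77 -12.43  -3.70 -12.58  -7.88  -6.88  -7.40  -8.41  -5.41
CG                                              5.36  -4.96  -6.00   2.11  -4.66   1.61   0.99  -5.10  -1.98  -3.21
CU                                                     -2.28  -7.71  -5.84 -13.69  -5.61  -4.72  -3.83  -7.36  -5.21
GA                                                            -0.31  -6.58  -7.77  -5.38  -6.88  -8.31  -7.20  -9.83
GC                                                                    5.62  -5.79   1.21   1.82  -4.27  -0.86  -4.54
GG                                                                           -1.05  -4.88  -5.13 -10.98  -3.25  -8.93
GU                                                                                   3.47  -0.34  -6.25  -0.96  -6.55
UA                                                                                          4.97  -6.50   0.45  -4.81
UC                                                                                                 -2.98  -5.12  -4.39
UG                                                                                                         3.41  -5.97
UU                                                                                                                -3.08
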