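# RIBOSUM85-60 log-odds substitution matrices for RNA structural alignment
# (single-base 4x4 and base-pair 16x16), transcribed from the published
# RIBOSUM matrix set derived from ribosomal RNA alignments.
# Units: log-odds (bits-like scale as published). Symmetric.
bases
      A      C      G      U
A   2.22  -1.86  -1.46  -1.39
C  -1.86   1.16  -2.48  -1.05
G  -1.46  -2.48   1.03  -1.74
U  -1.39  -1.05  -1.74   1.65
pairs
        AA      AC      AG      AU      CA      CC      CG      CU      GA      GC      GG      GU      UA      UC      UG      UU
AA   -2.49   -7.04   -8.24   -4.32   -8.84  -14.37   -4.68  -12.64   -6.86   -5.03   -8.39   -5.84   -4.01  -11.32   -6.16   -9.05
AC   -7.04   -2.11   -8.89   -2.04   -9.37   -9.08   -5.86  -10.45   -9.73   -3.81  -11.05   -4.72   -5.33   -8.67   -6.93   -7.83
AG   -8.24   -8.89   -0.80   -5.13   -9.13  -10.02   -7.98  -12.43   -2.98   -3.86   -5.77   -5.97   -9.46   -9.18  -11.07   -3.63
AU   -4.32   -2.04   -5.13    4.49   -5.56   -6.71    1.67   -5.17   -5.33    2.70   -5.61    0.59    1.61   -4.81   -2.98   -3.39
CA   -8.84   -9.37   -9.13   -5.56   -5.13  -10.45   -7.71   -5.84  -13.49   -5.61  -12.83  -12.41   -5.30   -7.98   -5.77  -13.94
CC  -14.37   -9.08  -10.02   -6.71  -10.45   -3.59   -5.77   -7.88  -12.43   -5.30   -8.01   -6.33   -8.24   -7.53   -9.01   -5.30
CG   -4.68   -5.86   -7.98    1.67   -7.71   -5.77    5.36   -4.96   -9.16    2.11   -6.30    1.61    0.60   -4.78   -1.05   -4.38
CU  -12.64  -10.45  -12.43   -5.17   -5.84   -7.88   -4.96   -2.42  -14.90   -3.83  -11.41   -5.30   -4.57   -6.88   -5.75   -5.61
GA   -6.86   -9.73   -2.98   -5.33  -13.49  -12.43   -9.16  -14.90   -0.27   -4.81   -4.99   -2.98   -9.91  -10.79   -7.45   -8.67
GC   -5.03   -3.81   -3.86    2.70   -5.61   -5.30    2.11   -3.83   -4.81    5.62   -5.77    1.21    1.53   -4.06   -3.70   -5.97
GG   -8.39  -11.05   -5.77   -5.61  -12.83   -8.01   -6.30  -11.41   -4.99   -5.77   -4.88   -3.47   -8.49   -7.32   -8.58   -7.71
GU   -5.84   -4.72   -5.97    0.59  -12.41   -6.33    1.61   -5.30   -2.98    1.21   -3.47    3.47   -2.09   -5.10   -4.04   -5.75
UA   -4.01   -5.33   -9.46    1.61   -5.30   -8.24    0.60   -4.57   -9.91    1.53   -8.49   -2.09    4.97   -3.83    1.93   -2.98
UC  -11.32   -8.67   -9.18   -4.81   -7.98   -7.53   -4.78   -6.88  -10.79   -4.06   -7.32   -5.10   -3.83   -3.21   -4.90   -4.45
UG   -6.16   -6.93  -11.07   -2.98   -5.77   -9.01   -1.05   -5.75   -7.45   -3.70   -8.58   -4.04    1.93   -4.90    3.36   -3.32
UU   -9.05   -7.83   -3.63   -3.39  -13.94   -5.30   -4.38   -5.61   -8.67   -5.97   -7.71   -5.75   -2.98   -4.45   -3.32    0.02
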