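# synthetic fixture codon usage table (burkholderia_like); values are NOT authoritative
AAA   8.0(   320)  AAC  29.5(  1180)  AAG  24.8(   992)  AAU   3.3(   132)
ACA   1.1(    44)  ACC  40.6(  1624)  ACG  18.8(   752)  ACU   5.1(   204)
AGA  12.8(   512)  AGC  28.2(  1128)  AGG  25.8(  1032)  AGU   5.0(   200)
AUA   3.5(   140)  AUC  43.7(  1748)  AUG  16.4(   656)  AUU   2.0(    80)
CAA   7.6(   304)  CAC  22.6(   904)  CAG  25.2(  1008)  CAU   6.8(   272)
CCA  13.9(   556)  CCC   7.5(   300)  CCG  38.2(  1528)  CCU   6.1(   244)
CGA   1.7(    68)  CGC  13.3(   532)  CGG  43.6(  1744)  CGU   1.3(    52)
CUA   3.7(   148)  CUC  38.8(  1552)  CUG  15.8(   632)  CUU  12.4(   496)
GAA   3.8(   152)  GAC  24.7(   988)  GAG  29.0(  1160)  GAU   8.1(   324)
GCA   2.1(    84)  GCC  38.6(  1544)  GCG  20.9(   836)  GCU   4.1(   164)
GGA   5.1(   204)  GGC  42.8(  1712)  GGG  11.2(   448)  GGU   6.4(   256)
GUA   4.7(   188)  GUC  14.2(   568)  GUG  45.2(  1808)  GUU   1.5(    60)
UAA   1.2(    48)  UAC  24.9(   996)  UAG   1.4(    56)  UAU   7.9(   316)
UCA   1.7(    68)  UCC  26.4(  1056)  UCG  34.7(  1388)  UCU   2.3(    92)
UGA   2.0(    80)  UGC  19.2(   768)  UGG  16.4(   656)  UGU   5.8(   232)
UUA  14.0(   560)  UUC  32.0(  1280)  UUG  13.7(   548)  UUU   0.8(    32)
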