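# synthetic fixture codon usage table (mouse_like); values are NOT authoritative
AAA   6.3(   252)  AAC   5.0(   200)  AAG  21.1(   844)  AAU  16.6(   664)
ACA  20.7(   828)  ACC   3.8(   152)  ACG  22.8(   912)  ACU  18.2(   728)
AGA   4.9(   196)  AGC  58.8(  2352)  AGG   6.0(   240)  AGU   9.0(   360)
AUA  15.9(   636)  AUC   8.7(   348)  AUG  16.4(   656)  AUU  24.6(   984)
CAA   5.8(   232)  CAC  27.9(  1116)  CAG  19.3(   772)  CAU   4.9(   196)
CCA   4.6(   184)  CCC   6.9(   276)  CCG  48.5(  1940)  CCU   5.7(   228)
CGA   8.7(   348)  CGC  22.9(   916)  CGG  44.3(  1772)  CGU  11.7(   468)
CUA   7.0(   280)  CUC  18.0(   720)  CUG  40.0(  1600)  CUU  13.2(   528)
GAA   7.5(   300)  GAC  19.7(   788)  GAG  25.3(  1012)  GAU   5.9(   236)
GCA   3.1(   124)  GCC  20.1(   804)  GCG  23.5(   940)  GCU  18.9(   756)
GGA   8.1(   324)  GGC  23.7(   948)  GGG  27.2(  1088)  GGU   6.6(   264)
GUA  14.6(   584)  GUC  18.5(   740)  GUG  18.1(   724)  GUU   5.6(   224)
UAA   0.8(    32)  UAC   6.2(   248)  UAG   0.8(    32)  UAU  20.6(   824)
UCA   6.7(   268)  UCC   5.8(   232)  UCG   8.6(   344)  UCU   9.5(   380)
UGA   1.0(    40)  UGC  29.7(  1188)  UGG  16.4(   656)  UGU   3.1(   124)
UUA   6.0(   240)  UUC  29.8(  1192)  UUG  12.0(   480)  UUU   3.0(   120)
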