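# synthetic fixture codon usage table (ecoli_like); values are NOT authoritative
AAA   8.3(   332)  AAC  26.1(  1044)  AAG  24.5(   980)  AAU   6.7(   268)
ACA  12.4(   496)  ACC   7.9(   316)  ACG  26.4(  1056)  ACU  14.6(   584)
AGA  18.7(   748)  AGC   6.8(   272)  AGG   3.5(   140)  AGU  17.6(   704)
AUA  11.8(   472)  AUC   8.7(   348)  AUG  16.4(   656)  AUU  28.6(  1144)
CAA   9.3(   372)  CAC  21.6(   864)  CAG  23.5(   940)  CAU   6.5(   260)
CCA   5.0(   200)  CCC  17.1(   684)  CCG  31.2(  1248)  CCU  12.2(   488)
CGA  33.2(  1328)  CGC  12.0(   480)  CGG  20.8(   832)  CGU  10.1(   404)
CUA   2.5(   100)  CUC  10.0(   400)  CUG  50.0(  2000)  CUU  19.5(   780)
GAA  18.6(   744)  GAC  18.2(   728)  GAG   5.6(   224)  GAU   5.5(   220)
GCA  36.1(  1444)  GCC   7.9(   316)  GCG  12.2(   488)  GCU   9.3(   372)
GGA   5.1(   204)  GGC  21.7(   868)  GGG  28.7(  1148)  GGU  10.2(   408)
GUA  22.1(   884)  GUC  17.3(   692)  GUG  15.1(   604)  GUU   6.6(   264)
UAA   1.8(    72)  UAC  27.9(  1116)  UAG   1.2(    48)  UAU   4.8(   192)
UCA  22.7(   908)  UCC  12.8(   512)  UCG  13.3(   532)  UCU  20.6(   824)
UGA   0.7(    28)  UGC  17.7(   708)  UGG  16.4(   656)  UGU   5.3(   212)
UUA  26.0(  1040)  UUC  20.9(   836)  UUG  17.0(   680)  UUU   6.3(   252)
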