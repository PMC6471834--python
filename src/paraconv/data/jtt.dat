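58
54 45
81 16 528
56 113 34 10
57 310 86 49 9
105 29 58 767 5 323
179 137 81 130 59 26 119
27 328 391 112 69 597 26 23
36 22 47 11 17 9 12 6 16
30 38 12 7 23 72 9 6 56 229
35 646 263 26 7 292 181 27 45 21 14
54 44 30 15 31 43 18 14 33 479 388 65
15 5 10 4 78 4 5 5 40 89 248 4 43
194 74 15 15 14 164 18 24 115 10 102 21 16 17
378 101 503 59 223 53 30 201 73 40 59 47 29 92 285
475 64 232 38 42 51 32 33 46 245 25 103 226 12 118 477
9 126 8 4 115 18 10 55 8 9 52 10 24 53 6 35 12
11 20 70 46 209 24 7 8 573 32 24 8 18 536 10 63 21 71
298 17 16 31 62 20 45 47 11 961 180 14 323 62 23 38 112 25 16

0.076747923 0.051690948 0.042644957 0.051543948 0.019802980 0.040751959 0.061829938 0.073151927 0.022943977 0.053760946 0.091903908 0.058675941 0.023825976 0.040125960 0.050900949 0.068764931 0.058564941 0.014260986 0.032101968 0.066004934

JTT empirical amino acid exchangeabilities and frequencies (Jones, Taylor & Thornton 1992), PAML dat layout, residue order A R N D C Q E G H I L K M F P S T W Y V.
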