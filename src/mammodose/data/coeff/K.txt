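# Photon mass interaction coefficients for K (Z=19, A=39.0983)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 3900.11 0.0184066 3.34741 3903.48 3900.11
1.06855 3289.92 0.0203255 3.31062 3293.25 3289.92
1.14181 2772.61 0.0223844 3.27113 2775.91 2772.61
1.22008 2333.5 0.0245858 3.22888 2336.75 2333.5
1.30372 1961.63 0.0269329 3.18379 1964.84 1961.63
1.39309 1647.84 0.0294297 3.13578 1651 1647.84
1.48859 1383.25 0.0320812 3.08476 1386.37 1383.25
1.5 1355.6 0.0323966 3.07869 1358.71 1355.6
1.59064 1159.94 0.0348939 3.03058 1163.01 1159.94
1.69969 971.972 0.0378753 2.9731 974.983 971.972
1.81621 813.945 0.0410342 2.91212 816.898 813.945
1.94071 681.186 0.0443788 2.84749 684.078 681.186
2 628.178 0.04596 2.8169 631.041 628.178
2.07375 569.732 0.0479163 2.77903 572.559 569.732
2.21592 476.224 0.0516517 2.70666 478.982 476.224
2.36782 397.823 0.0555856 2.63032 400.509 397.824
2.53015 332.13 0.0597141 2.55008 334.74 332.131
2.70359 277.119 0.0640272 2.4661 279.649 277.12
2.88893 231.08 0.068509 2.37868 233.528 231.081
3 208.331 0.071126 2.32755 210.73 208.332
3.08698 192.478 0.0731374 2.2882 194.839 192.478
3.2986 160.143 0.0778844 2.1952 162.416 160.144
3.52473 133.185 0.0827169 2.10029 135.368 133.186
3.6056 125.034 0.084383 2.0675 127.186 125.034
3.6092 1211.73 0.0844566 2.06606 1213.88 1074.87
3.76636 1081.98 0.0875971 2.00417 1084.07 964.875
4 926.635 0.092034 1.91652 928.644 832.205
4.02456 912.131 0.0924843 1.90761 914.131 819.746
4.30045 768.314 0.0973361 1.81141 770.223 695.488
4.59526 646.363 0.10211 1.71638 648.181 589.027
4.91028 543.107 0.106766 1.62328 544.837 498.021
5 517.784 0.108012 1.59829 519.49 475.572
5.2469 455.77 0.111268 1.53281 457.414 420.363
5.60659 381.984 0.115585 1.44552 383.545 354.213
5.99094 319.723 0.119696 1.36185 321.205 297.97
6 318.424 0.119787 1.35999 319.904 296.793
6.40163 267.267 0.123587 1.28205 268.673 250.251
6.84049 223.13 0.127253 1.20618 224.463 209.835
7.30942 186.024 0.130698 1.13415 187.289 175.652
7.81051 154.863 0.133933 1.06571 156.063 146.783
8 144.895 0.135055 1.04179 146.071 137.514
8.34594 128.789 0.136975 1.00054 129.927 122.501
8.397 126.617 0.137245 0.994696 127.749 120.473
8.91808 106.991 0.139839 0.938257 108.069 102.103
9.52944 88.7092 0.142544 0.878497 89.7302 84.9174
9.672 85.0542 0.143129 0.865426 86.0628 81.4725
10 77.3734 0.144418 0.836458 78.3542 74.2224
10.1827 73.4916 0.145103 0.820947 74.4576 70.5527
10.8808 60.8346 0.147525 0.765379 61.7475 58.5589
11.286 54.7936 0.148804 0.735529 55.6779 52.818
11.6267 50.3162 0.149815 0.711656 51.1776 48.5556
12.4237 41.582 0.151975 0.659735 42.3937 40.2215
13.2754 34.3355 0.153999 0.609652 35.0991 33.2853
14.1855 28.3283 0.155883 0.561508 29.0456 27.5186
15 24.0774 0.157353 0.522578 24.7573 23.4278
15.1579 23.3525 0.157616 0.515447 24.0256 22.7293
16.1971 19.2262 0.15919 0.471637 19.857 18.7474
17.3074 15.8124 0.160596 0.430246 16.4032 15.4454
18.4939 12.9965 0.161825 0.39142 13.5498 12.7159
19.7617 10.6754 0.162871 0.355265 11.1936 10.4614
20 10.3017 0.163041 0.349019 10.8138 10.098
21.1164 8.76333 0.163732 0.321834 9.24889 8.60074
22.564 7.18916 0.164407 0.291123 7.64469 7.06628
24.1109 5.89402 0.164897 0.26307 6.32199 5.8018
25 5.28665 0.165089 0.248834 5.70057 5.20812
25.7637 4.82913 0.165209 0.237568 5.23191 4.7606
27.5299 3.9499 0.165346 0.214475 4.32972 3.89974
28 3.75083 0.165354 0.208946 4.12513 3.70468
29.4172 3.22537 0.165317 0.19363 3.58431 3.18948
30 3.03747 0.165278 0.187868 3.39061 3.00515
31.4338 2.63284 0.165129 0.17486 2.97282 2.60799
33.5887 2.14842 0.164789 0.15799 2.4712 2.13215
35.8913 1.75252 0.164304 0.142848 2.05968 1.74295
38.3518 1.42909 0.16368 0.129273 1.72204 1.42476
40 1.25531 0.163216 0.121401 1.53992 1.25373
40.9809 1.16493 0.162926 0.117113 1.44497 1.16477
43.7903 0.949274 0.162045 0.106229 1.21755 0.952425
46.7922 0.773266 0.161044 0.0964958 1.03081 0.779098
50 0.629671 0.159928 0.087802 0.877401 0.637698
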