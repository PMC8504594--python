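# Photon mass interaction coefficients for W (Z=74, A=183.8400)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 3514.5 0.00648393 11.4508 3525.96 3514.5
1.06855 3081.1 0.00728212 11.3912 3092.5 3081.1
1.14181 2697.27 0.00816938 11.325 2708.6 2697.27
1.22008 2359.74 0.00915252 11.2515 2371 2359.74
1.30372 2062.92 0.0102382 11.1703 2074.1 2062.92
1.39309 1801.92 0.0114325 11.0809 1813.01 1801.92
1.48859 1572.45 0.0127412 10.9829 1583.45 1572.45
1.5 1547.89 0.0128994 10.971 1558.87 1547.89
1.59064 1370.78 0.0141691 10.8758 1381.67 1370.78
1.69969 1193.6 0.0157202 10.7594 1204.37 1193.6
1.80829 1047.42 0.0172831 10.642 1058.08 1047.42
1.81011 20296.6 0.0173093 10.6401 20307.3 20296.6
1.81621 17037.3 0.0173975 10.6334 17048 17037.3
1.87066 4696.77 0.018186 10.5742 4707.37 4696.77
1.87254 16974.9 0.0182131 10.5721 16985.4 16974.9
1.94071 4914.22 0.0192027 10.4977 4924.74 4914.22
2 3849.3 0.0200645 10.4328 3859.75 3849.3
2.07375 3525.43 0.0211368 10.3521 3535.8 3525.43
2.21592 2994.53 0.0231998 10.1965 3004.75 2994.53
2.27986 2789.49 0.0241243 10.1268 2799.64 2789.49
2.28214 3267.59 0.0241572 10.1243 3277.74 3267.59
2.36782 2962.73 0.025391 10.0311 2972.79 2962.73
2.53015 2520.44 0.0277096 9.85583 2530.33 2520.44
2.57361 2418.61 0.0283257 9.80921 2428.45 2418.61
2.57619 2581.36 0.0283621 9.80645 2591.19 2581.36
2.70359 2285.94 0.0301547 9.67067 2295.64 2285.94
2.81819 2071.43 0.0317497 9.54971 2081.01 2071.43
2.82101 2158.99 0.0317888 9.54675 2168.57 2158.99
2.88893 2040.85 0.0327259 9.47562 2050.36 2040.85
3 1867.61 0.034245 9.36021 1877.01 1867.61
3.08698 1744.88 0.035423 9.27062 1754.19 1744.88
3.2986 1489.08 0.0382464 9.05559 1498.17 1489.08
3.52473 1269.05 0.041196 8.83045 1277.92 1269.05
3.76636 1079.89 0.044271 8.59517 1088.53 1079.89
4 931.385 0.0471684 8.37293 939.805 931.386
4.02456 917.443 0.0474686 8.34988 925.84 917.443
4.30045 778.799 0.0507836 8.09486 786.945 778.799
4.59526 660.537 0.0542071 7.83069 668.422 660.538
4.91028 559.545 0.0577269 7.55819 567.161 559.546
5 534.679 0.0587028 7.48246 542.22 534.68
5.2469 473.571 0.0613272 7.27844 480.911 473.572
5.60659 400.431 0.0649895 6.99273 407.489 400.432
5.99094 338.324 0.0686936 6.70248 345.095 338.325
6 337.024 0.0687783 6.69582 343.789 337.025
6.40163 285.665 0.0724188 6.40915 292.147 285.667
6.84049 241.052 0.0761452 6.11416 247.242 241.053
7.30942 203.279 0.0798539 5.81881 209.177 203.28
7.81051 171.317 0.0835282 5.52426 176.925 171.319
8 161.018 0.0848452 5.41817 166.521 161.019
8.34594 144.288 0.0871531 5.23155 149.606 144.289
8.397 142.022 0.0874835 5.20475 147.314 142.024
8.91808 121.446 0.0907145 4.94162 126.479 121.448
9.52944 102.075 0.0941987 4.6554 106.825 102.077
9.672 98.1744 0.094967 4.5919 102.861 98.1765
10 89.936 0.0966748 4.45022 94.4829 89.9381
10.1827 85.7463 0.0975913 4.37387 90.2177 85.7485
10.2017 85.3264 0.0976851 4.36604 89.7902 85.3286
10.2119 234.961 0.0977355 4.36184 239.42 202.36
10.8808 193.204 0.100877 4.09815 197.403 168.046
11.286 174.917 0.102636 3.94902 178.968 152.958
11.5382 164.681 0.10368 3.86001 168.644 144.459
11.5498 228.524 0.103727 3.856 232.484 188.191
11.6267 224.441 0.104037 3.82946 228.374 185.09
12.0938 201.661 0.105848 3.67372 205.441 167.671
12.1059 232.643 0.105893 3.66981 236.419 187.775
12.4237 217.878 0.107055 3.56912 221.554 176.933
13.2754 183.885 0.109912 3.31844 187.313 151.546
14.1855 154.979 0.112592 3.07864 158.17 129.473
15 134.105 0.114701 2.8859 137.106 113.234
15.1579 130.5 0.115081 2.85071 133.465 110.401
16.1971 109.768 0.11737 2.63535 112.521 93.9483
17.3074 92.2577 0.119453 2.43292 94.8101 79.8157
18.4939 77.4827 0.12133 2.24346 79.8475 67.7049
19.7617 65.0252 0.123003 2.06671 67.2149 57.3472
20 62.9922 0.123284 2.03608 65.1515 55.6431
21.1164 54.5265 0.124477 1.90217 56.5531 48.5025
22.564 45.6882 0.125758 1.74924 47.5632 40.966
24.1109 38.2545 0.126854 1.60726 39.9886 34.5559
25 34.7085 0.127377 1.53411 36.37 31.473
25.7637 32.0092 0.127772 1.47558 33.6125 29.1145
27.5299 26.7566 0.128517 1.35365 28.2388 24.494
28 25.5544 0.128681 1.32402 27.0071 23.4302
29.4172 22.3451 0.129096 1.24099 23.7152 20.5786
30 21.1836 0.129236 1.20938 22.5222 19.5421
31.4338 18.654 0.129512 1.13721 19.9207 17.2759
33.5887 15.5668 0.129768 1.04193 16.7385 14.4926
35.8913 12.9855 0.12987 0.954835 14.0702 12.1491
38.3518 10.828 0.129821 0.875557 11.8334 10.1776
40 9.64676 0.129714 0.829127 10.6056 9.09275
40.9809 9.02535 0.129627 0.803711 9.95869 8.5204
43.7903 7.51967 0.129291 0.738868 8.38783 7.12846
46.7922 6.26082 0.12882 0.68056 7.0702 5.95863
50 5.21062 0.128221 0.62829 5.96714 4.97802
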