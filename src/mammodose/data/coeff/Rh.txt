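# Photon mass interaction coefficients for Rh (Z=45, A=102.9055)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 5931.38 0.00865076 7.49212 5938.89 5931.38
1.06855 5109.83 0.00973365 7.44297 5117.28 5109.83
1.14181 4394.88 0.0109346 7.38842 4402.28 4394.88
1.22008 3774.6 0.0122625 7.32808 3781.94 3774.6
1.30372 3234.34 0.0137258 7.26153 3241.62 3234.34
1.39309 2767.87 0.0153329 7.18839 2775.08 2767.87
1.48859 2366.33 0.0170917 7.10828 2373.45 2366.33
1.5 2323.87 0.0173042 7.09859 2330.99 2323.87
1.59064 2021.05 0.0190092 7.02086 2028.09 2021.05
1.69969 1724.41 0.021092 6.92582 1731.36 1724.41
1.81621 1469.81 0.0233455 6.82288 1476.66 1469.81
1.94071 1251.5 0.0257743 6.71181 1258.24 1251.5
2 1162.96 0.0269354 6.65867 1169.65 1162.96
2.07375 1064.18 0.0283817 6.59244 1070.8 1064.18
2.21592 903.69 0.0311697 6.46463 910.186 903.69
2.36782 766.735 0.0341387 6.32834 773.097 766.735
2.53015 649.978 0.037287 6.1836 656.199 649.978
2.70359 550.518 0.0406106 6.03056 556.59 550.519
2.88893 465.893 0.0441025 5.86948 471.806 465.893
3 423.53 0.0461607 5.7744 429.35 423.53
3.0028 422.52 0.0462122 5.77202 428.338 422.52
3.0058 1481.63 0.0462675 5.76946 1487.44 1481.63
3.08698 1393.45 0.0477528 5.70078 1399.19 1393.45
3.14453 1334.07 0.048796 5.6525 1339.77 1334.07
3.14767 1833.47 0.0488528 5.64987 1839.17 1833.47
3.2986 1631.06 0.0515476 5.52502 1636.64 1631.06
3.41019 1495.17 0.053501 5.4344 1500.66 1495.17
3.41361 1715.76 0.0535602 5.43165 1721.24 1715.76
3.52473 1582.98 0.0554699 5.34295 1588.38 1582.98
3.76636 1340.28 0.0594992 5.15544 1345.5 1340.28
4 1151.24 0.0632298 4.98138 1156.28 1151.24
4.02456 1133.49 0.0636124 4.96351 1138.51 1133.49
4.30045 957.088 0.067784 4.76825 961.924 957.089
4.59526 807.057 0.0719876 4.57084 811.7 807.058
4.91028 679.727 0.0761958 4.37247 684.176 679.728
5 648.474 0.0773422 4.31829 652.87 648.475
5.2469 571.895 0.0803815 4.17434 576.149 571.896
5.60659 480.679 0.0845184 3.97762 484.741 480.68
5.99094 403.6 0.0885814 3.78341 407.472 403.602
6 401.991 0.088673 3.77902 405.858 401.992
6.40163 338.448 0.0925477 3.59271 342.134 338.45
6.84049 283.541 0.0963977 3.40638 287.043 283.542
7.30942 237.332 0.100116 3.2251 240.657 237.334
7.81051 198.509 0.103691 3.04931 201.662 198.511
8 186.062 0.104948 2.98715 189.154 186.063
8.34594 165.917 0.107119 2.87919 168.903 165.919
8.397 163.196 0.107427 2.86383 166.168 163.198
8.91808 138.574 0.110398 2.7147 141.399 138.576
9.52944 115.583 0.113533 2.55558 118.252 115.585
9.672 110.972 0.114216 2.52064 113.607 110.974
10 101.264 0.115725 2.44307 103.822 101.266
10.1827 96.3481 0.11653 2.40145 98.8661 96.3506
10.8808 80.276 0.119396 2.25191 82.6473 80.2787
11.286 72.5765 0.120923 2.17127 74.8687 72.5795
11.6267 66.8559 0.122136 2.10661 69.0846 66.8589
12.4237 55.6547 0.124752 1.96539 57.7448 55.6579
13.2754 46.3048 0.127242 1.82825 48.2603 46.3083
14.1855 38.4937 0.1296 1.6954 40.3187 38.4975
15 32.9337 0.131475 1.58716 34.6523 32.9377
15.1579 31.9817 0.131815 1.56724 33.6807 31.9857
16.1971 26.558 0.133877 1.44426 28.1361 26.5624
17.3074 22.0487 0.135773 1.327 23.5115 22.0534
18.4939 18.3003 0.137491 1.21601 19.6538 18.3053
19.7617 15.185 0.139022 1.11173 16.4357 15.1904
20 14.6809 0.139278 1.09362 15.9137 14.6863
21.1164 12.5964 0.140358 1.01448 13.7512 12.6022
22.564 10.4459 0.141495 0.924447 11.5119 10.4521
23.2083 9.64687 0.141918 0.888408 10.6772 9.65318
23.2315 64.1788 0.141932 0.887152 65.2078 24.5493
24.1109 57.7992 0.142433 0.841634 58.7833 23.4118
25 52.5222 0.142862 0.799413 53.4644 22.3867
25.7637 48.5555 0.143175 0.765911 49.4646 21.5227
27.5299 40.787 0.143724 0.697021 41.6277 19.5379
28 39.0001 0.143834 0.680485 39.8244 19.0236
29.4172 34.2087 0.144088 0.634612 34.9874 17.5322
30 32.4666 0.144161 0.61733 33.2281 16.9475
31.4338 28.6441 0.144275 0.578268 29.3667 15.5783
33.5887 23.9539 0.144292 0.527533 24.6257 13.7307
35.8913 20.0124 0.144149 0.481935 20.6385 12.0217
38.3518 16.7035 0.143855 0.441007 17.2883 10.4644
40 14.8859 0.143593 0.417252 15.4468 9.55654
40.9809 13.9281 0.143417 0.404304 14.4758 9.06205
43.7903 11.6026 0.142844 0.371413 12.1168 7.81178
46.7922 9.6546 0.142142 0.341961 10.1387 6.70551
50 8.01911 0.141318 0.315613 8.47604 5.72977
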