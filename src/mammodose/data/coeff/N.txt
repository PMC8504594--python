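# Photon mass interaction coefficients for N (Z=7, A=14.0067)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 3169.34 0.0157248 1.29083 3170.65 3169.34
1.06855 2644 0.0177185 1.27676 2645.29 2644
1.14181 2203.49 0.019942 1.26105 2204.77 2203.49
1.22008 1834.5 0.0224143 1.24357 1835.76 1834.5
1.30372 1525.74 0.0251537 1.22419 1526.99 1525.74
1.39309 1267.65 0.0281773 1.20279 1268.88 1267.65
1.48859 1052.14 0.0315003 1.17924 1053.35 1052.14
1.5 1029.75 0.0319026 1.17639 1030.96 1029.75
1.59064 872.382 0.0351351 1.15347 873.571 872.383
1.69969 722.086 0.0390898 1.1254 723.251 722.086
1.81621 597.105 0.0433677 1.095 598.243 597.105
1.94071 493.346 0.047966 1.06229 494.456 493.346
2 452.282 0.0501561 1.0467 453.379 452.282
2.07375 407.279 0.0528743 1.02734 408.359 407.279
2.21592 335.947 0.0580746 0.990259 336.995 335.947
2.36782 276.879 0.0635402 0.951231 277.893 276.879
2.53015 228.006 0.0692359 0.910497 228.985 228.006
2.70359 187.603 0.0751184 0.868353 188.547 187.604
2.88893 154.232 0.0811378 0.825148 155.138 154.232
3 137.915 0.0846026 0.800238 138.8 137.916
3.08698 126.64 0.0872387 0.781265 127.509 126.641
3.2986 103.853 0.0933632 0.73711 104.684 103.854
3.52473 85.1071 0.0994527 0.693091 85.8997 85.108
3.76636 69.6959 0.105451 0.649604 70.451 69.6969
4 58.1025 0.110773 0.610897 58.8241 58.1035
4.02456 57.0355 0.111306 0.607012 57.7538 57.0365
4.30045 46.6421 0.116972 0.565637 47.3247 46.6433
4.59526 38.1159 0.12241 0.525751 38.7641 38.1173
4.91028 31.1266 0.127589 0.487573 31.7417 31.128
5 29.4479 0.128955 0.477467 30.0543 29.4494
5.2469 25.401 0.132485 0.451269 25.9848 25.4026
5.60659 20.7142 0.137082 0.416961 21.2682 20.7159
5.99094 16.8802 0.141366 0.384724 17.4063 16.8821
6 16.8015 0.14146 0.384014 17.327 16.8034
6.40163 13.7463 0.145334 0.354596 14.2462 13.7484
6.84049 11.1863 0.148984 0.326576 11.6619 11.1886
7.30942 9.09671 0.152321 0.300626 9.54966 9.09913
7.81051 7.39162 0.155353 0.276677 7.82365 7.39422
8 6.85604 0.156378 0.268491 7.28091 6.85872
8.34594 6.00221 0.158096 0.254625 6.41493 6.00501
8.397 5.88818 0.158334 0.252687 6.29921 5.891
8.91808 4.87108 0.160564 0.234344 5.26599 4.87408
9.52944 3.9446 0.162776 0.215688 4.32307 3.94782
9.672 3.76242 0.163239 0.211717 4.13737 3.76568
10 3.38313 0.164236 0.203061 3.75043 3.38651
10.1827 3.19338 0.164753 0.198506 3.55664 3.19682
10.8808 2.58443 0.166514 0.182649 2.93359 2.58811
11.286 2.29951 0.167399 0.174419 2.64133 2.30333
11.6267 2.09097 0.168076 0.167976 2.42702 2.0949
12.4237 1.69121 0.169455 0.154364 2.01503 1.6954
13.2754 1.36746 0.170662 0.141707 1.67983 1.37193
14.1855 1.10535 0.17171 0.129916 1.40698 1.11012
15 0.923814 0.172475 0.120606 1.2169 0.928837
15.1579 0.893216 0.172607 0.118919 1.18474 0.898289
16.1971 0.721573 0.173358 0.108656 1.00359 0.726972
17.3074 0.582737 0.173968 0.0990796 0.855785 0.588478
18.4939 0.470472 0.174443 0.0901524 0.735066 0.476573
19.7617 0.379719 0.174783 0.0818434 0.636346 0.386199
20 0.365279 0.17483 0.0804053 0.620514 0.371829
21.1164 0.30638 0.174991 0.0741268 0.555498 0.313256
22.564 0.247131 0.175069 0.0669792 0.48918 0.254421
24.1109 0.19928 0.17502 0.060378 0.434677 0.207001
25 0.177158 0.174939 0.0569951 0.409092 0.185123
25.7637 0.160645 0.174844 0.0542998 0.389788 0.168817
27.5299 0.129335 0.174543 0.0487191 0.352597 0.137975
28 0.122331 0.174447 0.0473706 0.344149 0.131094
29.4172 0.103997 0.174122 0.0436092 0.321727 0.113123
30 0.0974984 0.173974 0.0421836 0.313656 0.106772
31.4338 0.0836193 0.173581 0.038943 0.296143 0.0932503
33.5887 0.0672323 0.172923 0.0346951 0.27485 0.0773851
35.8913 0.0540545 0.17215 0.0308453 0.257049 0.0647462
38.3518 0.043458 0.171262 0.0273818 0.242102 0.0547049
40 0.0378376 0.17064 0.0253843 0.233862 0.0494448
40.9809 0.0349373 0.170261 0.0243063 0.229504 0.0467548
43.7903 0.0280862 0.169143 0.0216381 0.218867 0.0404881
46.7922 0.0225777 0.167904 0.0194196 0.209902 0.0355758
50 0.0181489 0.166539 0.0177218 0.20241 0.0317522
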