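# Photon mass interaction coefficients for Ag (Z=47, A=107.8682)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 6784.24 0.00784413 7.83351 6792.08 6784.24
1.06855 5851.88 0.00883912 7.78635 5859.67 5851.88
1.14181 5039.64 0.00994568 7.73386 5047.38 5039.64
1.22008 4333.91 0.0111729 7.67561 4341.6 4333.91
1.30372 3721.1 0.0125299 7.61115 3728.72 3721.1
1.39309 3190.63 0.0140259 7.54004 3198.18 3190.63
1.48859 2731.8 0.0156696 7.46185 2739.28 2731.8
1.5 2682.93 0.0158687 7.45237 2690.4 2682.93
1.59064 2333.9 0.0174696 7.37614 2341.29 2333.9
1.69969 1991.93 0.019434 7.28253 1999.23 1991.93
1.81621 1698.37 0.0215701 7.18062 1705.58 1698.37
1.94071 1446.62 0.0238845 7.07009 1453.71 1446.62
2 1344.57 0.0249953 7.017 1351.61 1344.57
2.07375 1230.91 0.0263829 6.95064 1237.89 1230.92
2.21592 1046.27 0.0290695 6.82203 1053.12 1046.27
2.36782 888.233 0.0319469 6.68409 894.949 888.234
2.53015 753.145 0.0350159 6.53675 759.717 753.145
2.70359 638.035 0.0382745 6.38006 644.453 638.035
2.88893 540.065 0.0417179 6.2142 546.321 540.065
3 491.012 0.0437565 6.11587 497.171 491.012
3.08698 456.38 0.0453377 6.03952 462.465 456.381
3.2986 385.007 0.0491216 5.85655 390.913 385.008
3.34942 370.173 0.0500159 5.81325 376.036 370.173
3.35278 1222.96 0.0500746 5.8104 1228.82 1222.96
3.52194 1121.02 0.0530058 5.66831 1126.74 1121.02
3.52473 1524.5 0.0530536 5.66599 1530.22 1524.5
3.52546 1523.79 0.0530662 5.66538 1529.51 1523.79
3.76636 1300.18 0.0571139 5.46874 1305.7 1300.18
3.8039 1266.77 0.0577308 5.43872 1272.27 1266.77
3.8077 1454.2 0.0577931 5.43569 1459.69 1454.2
4 1284.78 0.060891 5.28477 1290.13 1284.78
4.02456 1265.23 0.0612793 5.26583 1270.56 1265.23
4.30045 1070.8 0.0655238 5.05847 1075.93 1070.81
4.59526 904.736 0.0698196 4.84791 909.654 904.737
4.91028 763.249 0.0741374 4.63552 767.958 763.25
5 728.433 0.0753164 4.57738 733.086 728.434
5.2469 642.989 0.0784473 4.42266 647.49 642.99
5.60659 541.098 0.0827194 4.21072 545.391 541.099
5.99094 454.889 0.0869245 4.00106 458.977 454.891
6 453.088 0.0870193 3.99632 457.171 453.089
6.40163 382.031 0.0910351 3.79495 385.917 382.033
6.84049 320.506 0.0950263 3.59355 324.194 320.507
7.30942 268.59 0.0988772 3.39782 272.086 268.591
7.81051 224.885 0.102572 3.20849 228.196 224.886
8 210.857 0.103867 3.14172 214.102 210.859
8.34594 188.143 0.1061 3.02602 191.275 188.145
8.397 185.074 0.106415 3.00958 188.19 185.076
8.91808 157.285 0.109457 2.85052 160.245 157.287
9.52944 131.295 0.112645 2.68187 134.089 131.297
9.672 126.082 0.113336 2.645 128.84 126.084
10 115.106 0.11486 2.56336 117.784 115.108
10.1827 109.547 0.11567 2.51968 112.182 109.549
10.8808 91.3549 0.118542 2.36344 93.8369 91.3576
11.286 82.6285 0.120062 2.27963 85.0282 82.6314
11.6267 76.1389 0.121268 2.21263 78.4728 76.1419
12.4237 63.4254 0.123856 2.06677 65.616 63.4286
13.2754 52.8111 0.12631 1.92559 54.863 52.8146
14.1855 43.9533 0.128631 1.78898 45.8709 43.957
15 37.6392 0.130478 1.67759 39.4473 37.6432
15.1579 36.5581 0.130813 1.65707 38.346 36.5622
16.1971 30.3852 0.132851 1.53016 32.0483 30.3896
17.3074 25.2397 0.134733 1.40864 26.783 25.2443
18.4939 20.958 0.136451 1.29299 22.3874 20.963
19.7617 17.3979 0.137994 1.18367 18.7196 17.4033
20 16.8217 0.138253 1.16461 18.1246 16.8271
21.1164 14.4386 0.139353 1.08107 15.659 14.4443
22.564 11.9791 0.140524 0.985473 13.1051 11.9852
24.1109 9.93549 0.141503 0.897023 10.974 9.94199
25 8.96938 0.141956 0.851736 9.96308 8.97611
25.5012 8.47989 0.14218 0.827808 9.44988 8.48674
25.5268 55.248 0.142191 0.82662 56.2168 20.3365
25.7637 53.7169 0.142289 0.815711 54.6749 20.0855
27.5299 45.053 0.142886 0.74139 45.9373 18.6575
28 43.0947 0.143009 0.723504 43.9613 18.2709
29.4172 37.8409 0.143298 0.673798 38.658 17.0951
30 35.9296 0.143385 0.65504 36.7281 16.615
31.4338 31.7477 0.143531 0.612583 32.5039 15.4612
33.5887 26.602 0.143593 0.557332 27.3029 13.833
35.8913 22.2554 0.143493 0.507595 22.9064 12.2604
38.3518 18.6013 0.143237 0.462908 19.2075 10.7859
40 16.592 0.142998 0.436959 17.172 9.90974
40.9809 15.5324 0.142835 0.422812 16.0981 9.42767
43.7903 12.9574 0.142295 0.386869 13.4866 8.19415
46.7922 10.7988 0.141623 0.354672 11.2951 7.0866
50 8.99099 0.140826 0.325852 9.45766 6.10154
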