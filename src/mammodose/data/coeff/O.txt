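# Photon mass interaction coefficients for O (Z=8, A=15.9994)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 4419.04 0.0125674 1.50146 4420.56 4419.04
1.06855 3706.18 0.0142138 1.48817 3707.68 3706.18
1.14181 3104.78 0.0160573 1.47329 3106.27 3104.78
1.22008 2598.01 0.0181162 1.45666 2599.48 2598.01
1.30372 2171.48 0.0204089 1.43812 2172.93 2171.48
1.39309 1812.9 0.022954 1.41753 1814.34 1812.9
1.48859 1511.81 0.0257691 1.39474 1513.23 1511.81
1.5 1480.43 0.0261112 1.39197 1481.84 1480.43
1.59064 1259.29 0.0288705 1.3696 1260.69 1259.29
1.69969 1047.75 0.0322722 1.34201 1049.12 1047.75
1.81621 870.747 0.0359855 1.31187 872.095 870.747
1.94071 722.82 0.0400172 1.2791 724.139 722.82
2 664 0.0419527 1.26335 665.305 664
2.07375 599.338 0.0443691 1.24368 600.626 599.339
2.21592 496.181 0.0490373 1.20565 497.435 496.181
2.36782 410.299 0.0540104 1.16508 411.518 410.3
2.53015 338.992 0.0592699 1.1221 340.173 338.992
2.70359 279.838 0.0647892 1.07693 280.98 279.839
2.88893 230.809 0.0705336 1.02984 231.909 230.809
3 206.772 0.0738867 1.00231 207.848 206.772
3.08698 190.122 0.0764613 0.981144 191.179 190.122
3.2986 156.394 0.0825237 0.931235 157.408 156.395
3.52473 128.556 0.0886677 0.880534 129.525 128.557
3.76636 105.597 0.0948363 0.829492 106.521 105.597
4 88.2716 0.100408 0.783255 89.1552 88.2726
4.02456 86.6745 0.100972 0.778571 87.554 86.6755
4.30045 71.0914 0.107018 0.728228 71.9266 71.0925
4.59526 58.2674 0.112919 0.678896 59.0593 58.2687
4.91028 47.722 0.118627 0.63097 48.4716 47.7234
5 45.1841 0.120147 0.618173 45.9225 45.1856
5.2469 39.0566 0.1241 0.584794 39.7655 39.0582
5.60659 31.9414 0.129301 0.540651 32.6113 31.9431
5.99094 26.1033 0.134205 0.498758 26.7363 26.1052
6 25.9833 0.134313 0.497831 26.6154 25.9851
6.40163 21.3167 0.138792 0.459262 21.9148 21.3187
6.84049 17.3951 0.143052 0.422242 17.9604 17.3973
7.30942 14.1846 0.146983 0.38772 14.7193 14.1869
7.81051 11.5581 0.150586 0.355666 12.0644 11.5607
8 10.7314 0.15181 0.344673 11.2279 10.7341
8.34594 9.41109 0.15387 0.326012 9.89097 9.41387
8.397 9.23452 0.154157 0.323402 9.71208 9.23731
8.91808 7.65724 0.156846 0.29866 8.11274 7.66022
9.52944 6.22518 0.159527 0.273491 6.6582 6.22839
9.672 5.94268 0.160089 0.268141 6.37091 5.94594
10 5.35343 0.161299 0.25649 5.77122 5.3568
10.1827 5.05628 0.161928 0.250373 5.46858 5.05972
10.8808 4.1012 0.164065 0.229161 4.49443 4.10488
11.286 3.65342 0.165137 0.218225 4.03678 3.65724
11.6267 3.32528 0.165955 0.209707 3.70094 3.32921
12.4237 2.69523 0.167615 0.191858 3.0547 2.69942
13.2754 2.18379 0.169061 0.175466 2.52832 2.18827
14.1855 1.76879 0.170308 0.160386 2.09949 1.77356
15 1.48076 0.171215 0.148611 1.80059 1.48579
15.1579 1.43216 0.171371 0.146489 1.75002 1.43724
16.1971 1.15919 0.172262 0.133658 1.46511 1.1646
17.3074 0.937927 0.172991 0.121794 1.23271 0.943674
18.4939 0.758633 0.173566 0.110813 1.04301 0.764738
19.7617 0.6134 0.173994 0.100646 0.888039 0.619881
20 0.590262 0.174056 0.0988904 0.863208 0.596813
21.1164 0.495798 0.17428 0.0912366 0.761314 0.502673
22.564 0.400603 0.174427 0.0825396 0.65757 0.407891
24.1109 0.323574 0.17444 0.0745181 0.572532 0.331292
25 0.287911 0.174391 0.0704109 0.532713 0.295872
25.7637 0.261265 0.174321 0.0671407 0.502726 0.269432
27.5299 0.210666 0.174071 0.0603797 0.445117 0.219301
28 0.199333 0.173986 0.0587488 0.432068 0.20809
29.4172 0.16964 0.173692 0.0542079 0.397541 0.178761
30 0.159108 0.173556 0.0524907 0.385155 0.168375
31.4338 0.136594 0.173188 0.0485971 0.35838 0.146218
33.5887 0.109977 0.172561 0.0435168 0.326055 0.120122
35.8913 0.0885406 0.171813 0.0389337 0.299288 0.099223
38.3518 0.071277 0.170949 0.0348125 0.277038 0.0825137
40 0.0621094 0.170341 0.0324199 0.26487 0.073706
40.9809 0.0573753 0.169971 0.0311162 0.258463 0.0691821
43.7903 0.0461815 0.168883 0.0278081 0.242873 0.0585736
46.7922 0.0371689 0.167689 0.0248523 0.22971 0.0501606
50 0.0299129 0.166392 0.0222146 0.21852 0.0435177
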