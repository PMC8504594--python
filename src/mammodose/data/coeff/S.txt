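# Photon mass interaction coefficients for S (Z=16, A=32.0650)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 2300.81 0.0156563 2.94661 2303.77 2300.81
1.06855 1933.83 0.0176175 2.91496 1936.76 1933.83
1.14181 1624.32 0.0197886 2.8799 1627.22 1624.32
1.22008 1363.48 0.0221827 2.84122 1366.34 1363.48
1.30372 1143.8 0.0248117 2.7987 1146.63 1143.8
1.39309 958.92 0.0276851 2.75221 961.7 958.92
1.48859 803.422 0.0308095 2.7016 806.155 803.422
1.5 787.194 0.0311855 2.69551 789.921 787.194
1.59064 672.725 0.0341881 2.64684 675.406 672.725
1.69969 562.942 0.0378193 2.58792 565.568 562.942
1.81621 470.783 0.0416971 2.52493 473.349 470.783
1.94071 393.466 0.0458095 2.45806 395.97 393.466
2 362.624 0.0477488 2.4265 365.098 362.624
2.07375 328.64 0.0501391 2.38757 331.078 328.641
2.21592 274.319 0.0546626 2.31382 276.688 274.32
2.36782 228.829 0.0593514 2.23726 231.126 228.83
2.47076 203.62 0.0624328 2.18688 205.869 203.62
2.47324 2179.02 0.0625058 2.18569 2181.26 2040.41
2.53015 2069.23 0.0641726 2.15841 2071.45 1940.57
2.70359 1752.78 0.0690891 2.07786 1754.92 1650.79
2.88893 1475.71 0.074062 1.99621 1477.78 1395.35
3 1338.28 0.0769012 1.94952 1340.31 1268.1
3.08698 1243.09 0.0790513 1.91412 1245.09 1179.74
3.2986 1046.33 0.0840176 1.8322 1048.25 996.43
3.52473 879.444 0.0889237 1.75104 881.284 840.192
3.76636 738.254 0.093736 1.67119 740.019 707.419
4 629.145 0.0979985 1.60022 630.843 604.402
4.02456 618.959 0.0984256 1.59309 620.65 594.765
4.30045 518.291 0.10297 1.51711 519.911 499.332
4.59526 433.414 0.107353 1.44349 434.965 418.577
4.91028 361.984 0.111567 1.37234 363.468 350.388
5 344.47 0.112688 1.35334 345.936 333.633
5.2469 301.663 0.115612 1.30366 303.082 292.62
5.60659 251.113 0.119494 1.23731 252.47 244.068
5.99094 208.825 0.123226 1.17308 210.121 203.343
6 207.946 0.123309 1.17163 209.241 202.496
6.40163 173.484 0.126822 1.11067 174.722 169.223
6.84049 143.98 0.1303 1.04981 145.16 140.67
7.30942 119.372 0.133673 0.990234 120.496 116.805
7.81051 98.8706 0.136951 0.931743 99.9393 96.8815
8 92.3362 0.138114 0.910841 93.3852 90.5228
8.34594 81.807 0.140138 0.87424 82.8214 80.2674
8.397 80.3896 0.140426 0.868999 81.399 78.886
8.91808 67.6185 0.143232 0.817722 68.5795 66.4284
9.52944 55.8129 0.146225 0.762283 56.7214 54.8944
9.672 53.4597 0.146881 0.750031 54.3566 52.5932
10 48.5231 0.148332 0.722756 49.3942 47.7628
10.1827 46.0328 0.149106 0.708095 46.89 45.3247
10.8808 37.9272 0.15186 0.655395 38.7344 37.3822
11.286 34.0591 0.153317 0.627068 34.8395 33.5879
11.6267 31.2016 0.154467 0.604459 31.9605 30.7831
12.4237 25.6527 0.15691 0.555576 26.3652 25.3319
13.2754 21.0775 0.159172 0.509021 21.7457 20.832
14.1855 17.3074 0.161237 0.465031 17.9337 17.1201
15 14.6539 0.162816 0.430113 15.2469 14.5051
15.1579 14.2028 0.163095 0.423786 14.7896 14.0603
16.1971 11.6477 0.164738 0.385389 12.1978 11.5398
17.3074 9.54626 0.166164 0.349871 10.0623 9.46513
18.4939 7.81901 0.167375 0.317192 8.30358 7.75851
19.7617 6.40021 0.168376 0.287249 6.85584 6.35566
20 6.17229 0.168535 0.282117 6.62294 6.13021
21.1164 5.23554 0.169173 0.259897 5.66461 5.20334
22.564 4.28007 0.169776 0.234965 4.68482 4.25746
24.1109 3.49675 0.170194 0.212267 3.87921 3.48159
25 3.13041 0.170348 0.200748 3.50151 3.11862
25.7637 2.85496 0.170436 0.191619 3.21701 2.84564
27.5299 2.32834 0.170512 0.172844 2.67169 2.32361
28 2.20971 0.170505 0.168331 2.54854 2.206
29.4172 1.89686 0.170428 0.155783 2.22307 1.89579
30 1.78511 0.170374 0.151043 2.10653 1.78496
31.4338 1.54469 0.170192 0.140295 1.85518 1.54653
33.5887 1.25736 0.16981 0.126252 1.55343 1.26157
35.8913 1.02304 0.169287 0.113545 1.30587 1.02919
38.3518 0.832027 0.168628 0.102073 1.10273 0.839796
40 0.729592 0.168141 0.0953899 0.993123 0.738263
40.9809 0.676385 0.167837 0.0917415 0.935964 0.685539
43.7903 0.549618 0.16692 0.082462 0.799 0.559978
46.7922 0.446415 0.16588 0.0741495 0.686444 0.457847
50 0.362432 0.164722 0.0667219 0.593876 0.374836
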