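# Photon mass interaction coefficients for P (Z=15, A=30.9738)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 1806.05 0.0168452 2.65615 1808.72 1806.05
1.06855 1516.89 0.0189034 2.62501 1519.53 1516.89
1.14181 1273.22 0.0211691 2.59071 1275.83 1273.22
1.22008 1068.03 0.0236521 2.55309 1070.6 1068.03
1.30372 895.349 0.0263604 2.51204 897.888 895.349
1.39309 750.127 0.0292985 2.46746 752.623 750.127
1.48859 628.07 0.032468 2.41933 630.522 628.071
1.5 615.337 0.0328476 2.41356 617.784 615.337
1.59064 525.548 0.035866 2.36768 527.952 525.549
1.69969 439.487 0.0394851 2.31263 441.839 439.488
1.81621 367.287 0.0433129 2.25433 369.584 367.287
1.94071 306.751 0.047332 2.19304 308.991 306.751
2 282.614 0.0492134 2.16433 284.827 282.614
2.07375 256.026 0.0515203 2.1291 258.206 256.026
2.14443 233.613 0.0536932 2.09589 235.762 233.613
2.14657 2603.17 0.0537586 2.09489 2605.32 2468.88
2.21592 2435.55 0.0558512 2.06289 2437.67 2313.84
2.36782 2064.14 0.0602945 1.99485 2066.19 1967.61
2.53015 1737.73 0.0648179 1.92546 1739.72 1661.68
2.70359 1462.74 0.0693875 1.85523 1464.66 1402.83
2.88893 1231.33 0.0739695 1.78467 1233.19 1184.14
3 1116.01 0.0765695 1.74455 1117.83 1074.82
3.08698 1035.39 0.0785316 1.71424 1037.19 998.254
3.2986 869.325 0.0830441 1.64439 871.052 840.143
3.52473 728.996 0.0874811 1.57551 730.659 706.095
3.76636 610.515 0.0918212 1.50791 612.115 592.567
4 519.173 0.0956638 1.44785 520.717 504.802
4.02456 510.658 0.0960491 1.44182 512.196 496.608
4.30045 426.589 0.100156 1.37735 428.067 415.606
4.59526 355.49 0.104138 1.31453 356.908 346.924
4.91028 295.949 0.108001 1.25329 297.31 289.276
5 281.45 0.109036 1.23682 282.796 275.218
5.2469 246.136 0.111753 1.19347 247.442 240.943
5.60659 204.505 0.115406 1.13484 205.756 200.468
5.99094 169.747 0.118976 1.07718 170.943 166.611
6 169.025 0.119057 1.07587 170.22 165.908
6.40163 140.755 0.122474 1.02026 141.898 138.322
6.84049 116.599 0.125909 0.963914 117.688 114.713
7.30942 96.4908 0.129285 0.908071 97.5281 95.0311
7.81051 79.7706 0.132598 0.85274 80.7559 78.6419
8 74.4487 0.133779 0.83288 75.4153 73.4205
8.34594 65.8815 0.13584 0.798029 66.8153 65.0098
8.397 64.729 0.136134 0.793033 65.6582 63.8779
8.91808 54.3554 0.138997 0.744129 55.2385 53.6831
9.52944 44.7719 0.14205 0.691302 45.6053 44.2545
9.672 42.8571 0.142718 0.679649 43.6795 42.3694
10 38.8456 0.144193 0.653748 39.6435 38.4184
10.1827 36.8248 0.144979 0.639855 37.6097 36.4275
10.8808 30.2703 0.147762 0.590116 31.0082 29.9656
11.286 27.162 0.149225 0.563535 27.8748 26.899
11.6267 24.8676 0.150376 0.542408 25.5603 24.6343
12.4237 20.4168 0.152803 0.497019 21.0667 20.2387
13.2754 16.7526 0.155027 0.454185 17.3618 16.617
14.1855 13.7377 0.157037 0.414068 14.3088 13.6349
15 11.6186 0.158559 0.382459 12.1596 11.5376
15.1579 11.2585 0.158828 0.376751 11.7941 11.1811
16.1971 9.22119 0.160397 0.342244 9.72383 9.16329
17.3074 7.54792 0.161748 0.310488 8.02016 7.50512
18.4939 6.17452 0.162886 0.281373 6.61878 6.1434
19.7617 5.04793 0.16382 0.254755 5.46651 5.02587
20 4.86709 0.163968 0.250197 5.28126 4.84644
21.1164 4.12437 0.164559 0.230471 4.5194 4.10936
22.564 3.36771 0.165111 0.208353 3.74118 3.35821
24.1109 2.74819 0.165485 0.188239 3.10191 2.74301
25 2.45875 0.165617 0.178045 2.80241 2.45554
25.7637 2.24125 0.165689 0.169977 2.57691 2.2395
27.5299 1.82581 0.165731 0.153429 2.14497 1.8268
28 1.7323 0.165717 0.149462 2.04748 1.7339
29.4172 1.48583 0.165617 0.138465 1.78991 1.48904
30 1.39784 0.165555 0.134324 1.69772 1.40163
31.4338 1.20865 0.165354 0.124968 1.49897 1.21368
33.5887 0.982754 0.164946 0.112827 1.26053 0.989307
35.8913 0.798739 0.164401 0.101932 1.06507 0.806586
38.3518 0.648903 0.163723 0.0921806 0.904807 0.657874
40 0.568625 0.163226 0.0865384 0.818389 0.578242
40.9809 0.52695 0.162917 0.0834703 0.773338 0.536919
43.7903 0.427734 0.16199 0.0757041 0.665428 0.438609
46.7922 0.34705 0.160946 0.0687897 0.576785 0.358762
50 0.281465 0.15979 0.0626412 0.503896 0.293966
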