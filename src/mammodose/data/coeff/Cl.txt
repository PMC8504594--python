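# Photon mass interaction coefficients for Cl (Z=17, A=35.4530)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 2687.27 0.0135553 3.03402 2690.32 2687.27
1.06855 2261.54 0.0152864 3.00434 2264.56 2261.54
1.14181 1901.25 0.0172109 2.97132 1904.24 1901.25
1.22008 1597.15 0.0193435 2.93471 1600.11 1597.15
1.30372 1340.79 0.0216977 2.89426 1343.71 1340.79
1.39309 1124.84 0.0242858 2.84977 1127.71 1124.84
1.48859 943.051 0.0271181 2.80103 945.879 943.051
1.5 924.071 0.0274602 2.79514 926.893 924.071
1.59064 790.138 0.0302021 2.74792 792.916 790.138
1.69969 661.6 0.0335417 2.69035 664.324 661.6
1.81621 553.622 0.0371368 2.62831 556.288 553.622
1.94071 462.977 0.0409822 2.56189 465.579 462.977
2 426.802 0.0428072 2.53033 429.375 426.802
2.07375 386.93 0.045067 2.49123 389.466 386.93
2.21592 323.17 0.049375 2.41663 325.636 323.17
2.36782 269.746 0.0538833 2.33843 272.138 269.746
2.53015 225.009 0.058564 2.25712 227.324 225.009
2.70359 187.569 0.0633837 2.17326 189.806 187.57
2.82099 166.857 0.0665292 2.11843 169.042 166.857
2.82381 1720.37 0.0666036 2.11714 1722.55 1584.82
2.88893 1630.58 0.0683048 2.08746 1632.73 1505
3 1481.63 0.0711346 2.03804 1483.74 1371.75
3.08698 1376.79 0.0732869 2.00041 1378.87 1277.56
3.2986 1160.32 0.0782879 1.91282 1162.32 1082.06
3.52473 976.799 0.0832659 1.82541 978.708 915.139
3.76636 821.515 0.0881802 1.73886 823.342 772.985
4 701.434 0.0925544 1.66157 703.188 662.418
4.02456 690.212 0.0929936 1.65379 691.959 652.054
4.30045 579.169 0.0976732 1.57078 580.837 549.204
4.59526 485.378 0.102192 1.49027 486.971 461.878
4.91028 406.262 0.10653 1.4126 407.781 387.854
5 386.909 0.107682 1.39191 388.408 369.693
5.2469 339.597 0.110676 1.33796 341.046 325.198
5.60659 283.503 0.114625 1.26641 284.884 272.254
5.99094 236.21 0.118381 1.19787 237.526 227.439
6 235.226 0.118464 1.19634 236.541 226.505
6.40163 196.589 0.121954 1.13213 197.843 189.758
6.84049 163.449 0.12536 1.0689 164.643 158.134
7.30942 135.757 0.128616 1.00787 136.893 131.626
7.81051 112.642 0.131737 0.948707 113.722 109.435
8 105.265 0.132835 0.927727 106.325 102.339
8.34594 93.3666 0.134737 0.891158 94.3925 90.8799
8.397 91.7638 0.135007 0.885938 92.7847 89.3347
8.91808 77.309 0.137625 0.835033 78.2816 75.3828
9.52944 63.9102 0.140405 0.780237 64.8309 62.4208
9.672 61.2368 0.141012 0.768146 62.1459 59.8309
10 55.6248 0.142356 0.741236 56.5084 54.3902
10.1827 52.7921 0.143073 0.726772 53.6619 51.6416
10.8808 43.5736 0.145625 0.67472 44.3939 42.6858
11.286 39.1844 0.146979 0.646674 39.978 38.4153
11.6267 35.9363 0.14805 0.624237 36.7086 35.2521
12.4237 29.6063 0.150334 0.575523 30.3322 29.0799
13.2754 24.3545 0.152465 0.528809 25.0358 23.9504
14.1855 20.022 0.154427 0.484326 20.6607 19.7123
15 16.9694 0.155941 0.448754 17.5741 16.7223
15.1579 16.4501 0.15621 0.442282 17.0485 16.2133
16.1971 13.507 0.157802 0.402844 14.0677 13.3265
17.3074 11.0836 0.159198 0.366118 11.6089 10.9465
18.4939 9.08937 0.160394 0.332143 9.5819 8.98577
19.7617 7.44929 0.161391 0.300891 7.91157 7.37155
20 7.18562 0.16155 0.295527 7.6427 7.11189
21.1164 6.10134 0.162193 0.272276 6.5358 6.04357
22.564 4.99416 0.162807 0.246163 5.40313 4.95184
24.1109 4.08533 0.16324 0.222384 4.47096 4.05498
25 3.65989 0.163404 0.210316 4.03361 3.6349
25.7637 3.33979 0.163502 0.200752 3.70404 3.31873
27.5299 2.7272 0.163601 0.181074 3.07188 2.7134
28 2.58907 0.163602 0.176339 2.92902 2.57686
29.4172 2.22455 0.163547 0.163157 2.55126 2.21644
30 2.09424 0.163502 0.158167 2.41591 2.08756
31.4338 1.81372 0.163347 0.146821 2.12389 1.81007
33.5887 1.47808 0.163009 0.131901 1.77299 1.47798
35.8913 1.204 0.16254 0.118257 1.48479 1.20675
38.3518 0.980284 0.161945 0.105769 1.248 0.985346
40 0.860187 0.161504 0.0983994 1.12009 0.866499
40.9809 0.797768 0.161228 0.0943426 1.05334 0.804736
43.7903 0.648932 0.160391 0.0839084 0.893231 0.6575
46.7922 0.527616 0.159438 0.0744234 0.761478 0.537553
50 0.428779 0.15837 0.065874 0.653023 0.43991
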