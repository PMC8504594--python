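# Photon mass interaction coefficients for Ar (Z=18, A=39.9480)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 3056.04 0.0114885 3.04133 3059.09 3056.04
1.06855 2572.8 0.0129754 3.01434 2575.82 2572.8
1.14181 2164.37 0.0146346 2.9842 2167.37 2164.37
1.22008 1819.46 0.0164807 2.95064 1822.43 1819.46
1.30372 1528.23 0.0185279 2.9134 1531.17 1528.23
1.39309 1282.34 0.0207899 2.87223 1285.23 1282.34
1.48859 1075.3 0.023279 2.82688 1078.15 1075.3
1.5 1053.68 0.0235806 2.82138 1056.52 1053.68
1.59064 901.105 0.0260056 2.77716 903.908 901.105
1.69969 754.654 0.0289775 2.72292 757.406 754.654
1.81621 631.609 0.0321994 2.66406 634.305 631.609
1.94071 528.3 0.0356716 2.60056 530.936 528.3
2 487.068 0.037329 2.57022 489.675 487.068
2.07375 441.619 0.0393895 2.53248 444.191 441.619
2.21592 368.935 0.0433434 2.45999 371.438 368.935
2.36782 308.026 0.0475172 2.38335 310.457 308.027
2.53015 257.016 0.0518892 2.30296 259.371 257.016
2.70359 214.322 0.0564316 2.21929 216.597 214.322
2.88893 178.609 0.0611112 2.13294 180.803 178.609
3 160.968 0.0638208 2.08286 163.115 160.969
3.08698 148.687 0.0658907 2.04456 150.797 148.687
3.2013 134.391 0.0685397 1.99549 136.455 134.391
3.2045 1339.45 0.0686127 1.99414 1341.51 1211.54
3.2986 1245.88 0.0707293 1.95489 1247.91 1130.3
3.52473 1051.7 0.0755847 1.86467 1053.64 960.394
3.76636 886.031 0.0804143 1.77469 887.886 814.041
4 757.595 0.0847414 1.69382 759.373 699.636
4.02456 745.584 0.0851773 1.68566 747.355 688.892
4.30045 626.751 0.0898358 1.59827 628.439 582.152
4.59526 526.276 0.0943564 1.51312 527.883 491.229
4.91028 441.327 0.0987113 1.43071 442.857 413.824
5 420.52 0.0998688 1.40873 422.029 394.784
5.2469 369.621 0.102879 1.35142 371.075 348.064
5.60659 309.171 0.106846 1.27549 310.554 292.297
5.99094 258.277 0.110606 1.20303 259.591 245.085
6 257.216 0.110689 1.20142 258.528 244.099
6.40163 215.474 0.114159 1.13402 216.722 205.175
6.84049 179.445 0.117512 1.0683 180.631 171.419
7.30942 149.288 0.120678 1.00561 150.414 143.039
7.81051 124.072 0.123673 0.945639 125.141 119.212
8 116.015 0.124717 0.924563 117.064 111.579
8.34594 103.009 0.126513 0.888058 104.024 99.2342
8.397 101.256 0.126767 0.88287 102.266 97.568
8.91808 85.4318 0.129212 0.832552 86.3936 82.5027
9.52944 70.7279 0.131784 0.778866 71.6385 68.4592
9.672 67.7911 0.132343 0.767073 68.6906 65.6489
10 61.6232 0.133577 0.740879 62.4976 59.7402
10.1827 58.5079 0.134235 0.726824 59.369 56.7524
10.8808 48.3604 0.136568 0.676338 49.1733 47.0033
11.286 43.523 0.137805 0.649157 44.31 42.3461
11.6267 39.9405 0.138783 0.627403 40.7067 38.8926
12.4237 32.9598 0.140873 0.580087 33.6808 32.1515
13.2754 27.1771 0.142832 0.534516 27.8545 26.5545
14.1855 22.3831 0.144648 0.490856 23.0186 21.9044
15 18.9876 0.146059 0.45571 19.5893 18.6045
15.1579 18.4096 0.146312 0.44929 19.0052 18.0423
16.1971 15.1323 0.147812 0.409995 15.6901 14.8511
17.3074 12.4309 0.149142 0.373125 12.9532 12.2162
18.4939 10.2055 0.150293 0.338789 10.6946 10.0421
19.7617 8.37346 0.151263 0.307041 8.83177 8.24954
20 8.07873 0.151419 0.301579 8.53173 7.96093
21.1164 6.86607 0.152052 0.277878 7.296 6.77268
22.564 5.62658 0.152662 0.251241 6.03049 5.55677
24.1109 4.60802 0.153097 0.227027 4.98814 4.55643
25 4.13079 0.153263 0.214778 4.49883 4.08734
25.7637 3.77151 0.153363 0.205101 4.12998 3.73402
27.5299 3.08492 0.153468 0.185306 3.4237 3.05836
28 2.93032 0.15347 0.180574 3.26437 2.90614
29.4172 2.52173 0.153419 0.16748 2.84263 2.50367
30 2.37544 0.153376 0.162558 2.69138 2.35952
31.4338 2.06008 0.153223 0.151454 2.36476 2.04865
33.5887 1.6819 0.152888 0.137068 1.97185 1.67567
35.8913 1.37229 0.152419 0.124166 1.64887 1.37016
38.3518 1.11897 0.151825 0.112605 1.3834 1.12012
40 0.982732 0.151385 0.105904 1.24002 0.985612
40.9809 0.911846 0.15111 0.102255 1.16521 0.915623
43.7903 0.742595 0.150279 0.0929974 0.985872 0.748516
46.7922 0.60438 0.149339 0.0847269 0.838446 0.612075
50 0.491582 0.148292 0.077348 0.717221 0.50077
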