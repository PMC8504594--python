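# Photon mass interaction coefficients for Ti (Z=22, A=47.8670)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 5635.8 0.0161756 3.69305 5639.51 5635.8
1.06855 4773.36 0.0180135 3.65226 4777.03 4773.36
1.14181 4038.54 0.0200082 3.60796 4042.17 4038.54
1.22008 3413.34 0.0221623 3.56009 3416.92 3413.34
1.30372 2881.92 0.0244766 3.50863 2885.45 2881.92
1.39309 2430.76 0.0269503 3.45357 2434.24 2430.76
1.48859 2048.19 0.0295806 3.39498 2051.61 2048.19
1.5 2008.08 0.0298932 3.38801 2011.5 2008.08
1.59064 1724.13 0.0323634 3.33293 1727.5 1724.13
1.69969 1449.96 0.0352937 3.26752 1453.26 1449.96
1.81621 1218.23 0.0383664 3.19886 1221.47 1218.23
1.94071 1022.14 0.0415762 3.12705 1025.3 1022.14
2 943.617 0.0430769 3.09344 946.754 943.617
2.07375 856.91 0.0449187 3.05217 860.007 856.91
2.21592 717.861 0.0483905 2.97428 720.884 717.861
2.36782 600.836 0.0519892 2.89342 603.781 600.836
2.53015 502.534 0.0557128 2.80962 505.399 502.534
2.70359 420.055 0.059559 2.72289 422.837 420.055
2.88893 350.896 0.0635242 2.63331 353.593 350.897
3 316.673 0.0658313 2.5811 319.32 316.673
3.08698 292.776 0.0676028 2.54097 295.384 292.776
3.2986 243.977 0.0717858 2.44605 246.495 243.978
3.52473 203.226 0.0760608 2.34879 205.65 203.226
3.76636 169.209 0.0804117 2.24952 171.539 169.209
4 143.235 0.0844099 2.15805 145.477 143.236
4.02456 140.825 0.0848184 2.14868 143.058 140.826
4.30045 117.151 0.0892572 2.04676 119.287 117.152
4.59526 97.4142 0.0937011 1.94435 99.4522 97.4152
4.91028 80.9658 0.0981199 1.84208 82.906 80.9669
4.96392 78.5457 0.0988393 1.82539 80.4699 78.5468
4.96888 708.657 0.0989055 1.82385 710.58 587.359
5 695.953 0.099318 1.81427 697.867 577.571
5.2469 607.867 0.102481 1.74067 609.71 509.335
5.60659 512.667 0.106752 1.64086 514.414 434.897
5.99094 431.752 0.110898 1.54336 433.406 370.459
6 430.057 0.11099 1.54117 431.709 369.098
6.40163 363.081 0.114888 1.44888 364.645 314.845
6.84049 304.798 0.118696 1.358 306.275 266.903
7.30942 255.526 0.122299 1.2712 256.92 225.796
7.81051 213.941 0.125684 1.1888 215.255 190.646
8 200.57 0.126852 1.16012 201.857 179.249
8.34594 178.89 0.128843 1.11093 180.13 160.662
8.397 175.958 0.129122 1.10399 177.191 158.138
8.91808 149.385 0.131777 1.03756 150.554 135.141
9.52944 124.56 0.134492 0.968507 125.663 113.446
9.672 119.575 0.135072 0.953607 120.664 109.063
10 109.062 0.136336 0.920858 110.119 99.7886
10.1827 103.71 0.137001 0.903478 104.751 95.0507
10.8808 86.2079 0.139319 0.8421 87.1894 79.4725
11.286 77.8221 0.14052 0.809671 78.7723 71.9607
11.6267 71.5933 0.14146 0.783983 72.5187 66.3595
12.4237 59.4052 0.143438 0.728762 60.2774 55.3421
13.2754 49.2496 0.145265 0.676135 50.071 46.0983
14.1855 40.7949 0.146949 0.625877 41.5677 38.3531
15 34.7885 0.148259 0.585289 35.5221 32.8204
15.1579 33.7621 0.148494 0.577847 34.4885 31.8722
16.1971 27.9174 0.149901 0.531982 28.5993 26.4562
17.3074 23.0642 0.151169 0.488282 23.7037 21.9359
18.4939 19.038 0.152294 0.446792 19.6371 18.1679
19.7617 15.7007 0.153272 0.407586 16.2616 15.0308
20 15.1617 0.153433 0.400749 15.7159 14.5229
21.1164 12.937 0.154099 0.370747 13.4619 12.4222
22.564 10.6481 0.15477 0.336347 11.1392 10.2533
24.1109 8.75732 0.155284 0.304434 9.21704 8.45539
25 7.86832 0.155497 0.288061 8.31188 7.60786
25.7637 7.19756 0.155638 0.275019 7.62822 6.96737
27.5299 5.90718 0.155835 0.248068 6.31108 5.73254
28 5.61479 0.15586 0.241573 6.01222 5.45221
29.4172 4.84133 0.155876 0.223507 5.22071 4.70966
30 4.56413 0.155858 0.216682 4.93667 4.44318
31.4338 3.96596 0.155765 0.201224 4.32295 3.86744
33.5887 3.24737 0.155507 0.181083 3.58397 3.17441
35.8913 2.65775 0.155109 0.162932 2.97579 2.60453
38.3518 2.17417 0.154575 0.146611 2.47535 2.13623
40 1.91353 0.154168 0.13713 2.20483 1.88346
40.9809 1.77774 0.153912 0.131962 2.06361 1.75165
43.7903 1.45291 0.153125 0.118831 1.72486 1.43603
46.7922 1.18687 0.152219 0.107074 1.44616 1.17719
50 0.969084 0.151201 0.0965564 1.21684 0.965063
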