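# Photon mass interaction coefficients for Al (Z=13, A=26.9815)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 1100.31 0.0193329 2.25663 1102.58 1100.31
1.06855 922.746 0.0215406 2.22768 924.995 922.746
1.14181 773.388 0.0239387 2.19621 775.608 773.388
1.22008 647.824 0.0265288 2.1622 650.013 647.824
1.30372 542.321 0.0293093 2.12566 544.476 542.321
1.39309 453.634 0.0322749 2.08666 455.753 453.634
1.48859 379.002 0.0354164 2.04531 381.083 379.003
1.5 371.231 0.0357888 2.0404 373.307 371.231
1.55882 334.395 0.0376973 2.01526 336.448 334.395
1.56038 4068.54 0.0377476 2.01459 4070.6 3937.54
1.59064 3973.25 0.0387207 2.00177 3975.29 3847.75
1.69969 3455.06 0.0421708 1.95626 3457.06 3352.93
1.81621 2908.04 0.0457473 1.90903 2909.99 2827.59
1.94071 2446.64 0.0494283 1.86037 2448.55 2383.3
2 2261.84 0.0511272 1.83788 2263.73 2205.02
2.07375 2059.76 0.0531911 1.81055 2061.62 2009.85
2.21592 1735.55 0.057014 1.75985 1737.37 1696.2
2.36782 1460.14 0.0608769 1.70854 1461.91 1429.16
2.53015 1226.62 0.0647628 1.65683 1228.34 1202.26
2.70359 1028.92 0.0686588 1.60487 1030.59 1009.8
2.88893 861.798 0.0725561 1.55278 863.424 846.811
3 778.612 0.074772 1.52311 780.21 765.573
3.08698 720.686 0.0764499 1.50061 722.263 708.957
3.2986 601.191 0.0803391 1.44836 602.719 592.034
3.52473 500.917 0.084225 1.39599 502.397 493.777
3.76636 416.966 0.0881111 1.34345 418.398 411.405
4 352.715 0.0916423 1.29556 354.102 348.286
4.02456 346.747 0.0920017 1.29067 348.13 342.42
4.30045 288.075 0.0959021 1.23756 289.408 284.71
4.59526 239.097 0.099817 1.18403 240.381 236.484
4.91028 198.254 0.10375 1.13001 199.488 196.226
5 188.336 0.104828 1.11517 189.556 186.444
5.2469 164.227 0.107704 1.07546 165.41 162.656
5.60659 135.908 0.111674 1.02039 137.04 134.691
5.99094 112.361 0.115654 0.964878 113.442 111.42
6 111.874 0.115745 0.963608 112.953 110.938
6.40163 92.8033 0.119631 0.909079 93.832 92.0766
6.84049 76.5678 0.123583 0.853239 77.5447 76.0073
7.30942 63.0953 0.127486 0.797684 64.0205 62.6637
7.81051 51.9542 0.131308 0.742803 52.8283 51.6222
8 48.4211 0.132664 0.72321 49.277 48.1193
8.34594 42.748 0.135017 0.689024 43.5721 42.4931
8.397 41.9863 0.135352 0.684148 42.8058 41.7376
8.91808 35.1447 0.138579 0.636783 35.92 34.9493
9.52944 28.8253 0.141963 0.586494 29.5538 28.6762
9.672 27.5717 0.142694 0.575538 28.2899 27.4314
10 24.9488 0.144295 0.551372 25.6445 24.8265
10.1827 23.6295 0.145141 0.538518 24.3131 23.516
10.8808 19.3597 0.148092 0.493139 20.0009 19.2736
11.286 17.3405 0.149617 0.4693 17.9595 17.2669
11.6267 15.8527 0.150801 0.450554 16.4541 15.7879
12.4237 12.974 0.153259 0.410862 13.5381 12.9255
13.2754 10.6122 0.155465 0.374079 11.1417 10.5762
14.1855 8.67555 0.157423 0.340145 9.17311 8.64934
15 7.31858 0.158884 0.313697 7.79116 7.29884
15.1579 7.08841 0.15914 0.308945 7.5565 7.06975
16.1971 5.78844 0.160625 0.280331 6.22939 5.77564
17.3074 4.72425 0.16189 0.254137 5.14027 4.71603
18.4939 3.85357 0.162944 0.230194 4.24671 3.84895
19.7617 3.1416 0.163799 0.208344 3.51375 3.13984
20 3.02754 0.163933 0.204606 3.39608 3.02622
21.1164 2.55975 0.164464 0.18844 2.91266 2.56027
22.564 2.0845 0.164947 0.170347 2.41979 2.08686
24.1109 1.69654 0.165255 0.153943 2.01573 1.70042
25 1.5157 0.165352 0.145656 1.82671 1.52031
25.7637 1.38001 0.165395 0.139113 1.68451 1.38517
27.5299 1.12181 0.165375 0.125747 1.41294 1.12807
28 1.06391 0.165345 0.122556 1.35181 1.07041
29.4172 0.911378 0.1652 0.113735 1.19031 0.918586
30 0.856966 0.16512 0.110425 1.13251 0.864435
31.4338 0.740056 0.164878 0.10297 1.0079 0.748118
33.5887 0.600646 0.164415 0.0933442 0.858405 0.609488
35.8913 0.487259 0.163817 0.0847551 0.735831 0.496829
38.3518 0.395083 0.163091 0.0771027 0.635277 0.405346
40 0.345767 0.162566 0.0726893 0.581022 0.356456
40.9809 0.320188 0.162242 0.0702934 0.552723 0.331119
43.7903 0.259363 0.161276 0.0642407 0.48488 0.270948
46.7922 0.209991 0.160197 0.0588656 0.429053 0.222219
50 0.169933 0.159011 0.0540966 0.383041 0.182801
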