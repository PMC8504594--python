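# Photon mass interaction coefficients for Si (Z=14, A=28.0855)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 1467.64 0.019089 2.52713 1470.18 1467.64
1.06855 1232.01 0.0213425 2.4953 1234.53 1232.01
1.14181 1033.58 0.0238054 2.4605 1036.06 1033.58
1.22008 866.575 0.0264835 2.42263 869.024 866.575
1.30372 726.108 0.0293796 2.38165 728.519 726.108
1.39309 608.033 0.0324928 2.33756 610.403 608.033
1.48859 508.838 0.0358183 2.29042 511.164 508.838
1.5 498.493 0.0362144 2.2848 500.814 498.493
1.59064 425.555 0.039347 2.24036 427.835 425.555
1.69969 355.672 0.0430648 2.18756 357.903 355.673
1.81621 297.068 0.0469539 2.13226 299.248 297.069
1.83798 287.588 0.0476695 2.12208 289.757 287.588
1.83982 3345.8 0.0477297 2.12122 3347.97 3208.25
1.94071 3016.84 0.0509922 2.07478 3018.97 2899.26
2 2790.72 0.0528674 2.04806 2792.82 2685.18
2.07375 2540.73 0.0551544 2.01545 2542.8 2448.06
2.21592 2139.04 0.0594132 1.95465 2141.05 2066.02
2.36782 1800.26 0.0637401 1.89278 1802.21 1742.75
2.53015 1516.54 0.0681072 1.83023 1518.44 1471.2
2.70359 1276.01 0.0724873 1.76736 1277.85 1240.31
2.88893 1072.03 0.0768564 1.70451 1073.81 1043.96
3 970.24 0.0793289 1.66887 971.988 945.778
3.08698 899.122 0.0811931 1.64197 900.845 877.092
3.2986 752.917 0.0854803 1.57997 754.583 735.653
3.52473 629.728 0.0897054 1.51869 631.337 616.216
3.76636 525.799 0.0938603 1.45822 527.351 515.24
4 445.628 0.0975686 1.40405 447.13 437.202
4.02456 438.174 0.0979424 1.39858 439.67 429.94
4.30045 364.797 0.101954 1.33973 366.239 358.382
4.59526 303.411 0.105902 1.28156 304.799 298.418
4.91028 252.109 0.109796 1.2239 253.442 248.226
5 239.633 0.110851 1.20822 240.952 236.009
5.2469 209.275 0.113647 1.16656 210.555 206.259
5.60659 173.547 0.117466 1.10938 174.774 171.207
5.99094 143.777 0.12126 1.05224 144.95 141.963
6 143.16 0.121346 1.05093 144.332 141.357
6.40163 118.996 0.12503 0.995065 120.116 117.592
6.84049 98.389 0.128772 0.937911 99.4557 97.303
7.30942 81.27 0.132474 0.880912 82.2834 80.4311
7.81051 67.0629 0.136119 0.824298 68.0233 66.4157
8 62.5463 0.137418 0.803982 63.4877 61.9573
8.34594 55.2802 0.139683 0.768376 56.1883 54.7817
8.397 54.3039 0.140006 0.763279 55.2072 53.8173
8.91808 45.5267 0.143141 0.713509 46.3834 45.1433
9.52944 37.4 0.146463 0.66009 38.2066 37.1061
9.672 35.7862 0.147186 0.648366 36.5817 35.5093
10 32.4077 0.148778 0.622392 33.1789 32.1657
10.1827 30.7072 0.149623 0.608511 31.4654 30.4823
10.8808 25.1983 0.152594 0.559134 25.9101 25.0266
11.286 22.59 0.154144 0.532961 23.2771 22.4422
11.6267 20.6664 0.155355 0.512266 21.334 20.5357
12.4237 16.9402 0.157889 0.468135 17.5663 16.8411
13.2754 13.8782 0.160186 0.426885 14.4653 13.8035
14.1855 11.3634 0.162242 0.388572 11.9142 11.3075
15 9.59869 0.163786 0.358574 10.121 9.55521
15.1579 9.29912 0.164057 0.353173 9.81635 9.25769
16.1971 7.6056 0.165636 0.320603 8.09184 7.5754
17.3074 6.21703 0.166987 0.29073 6.67474 6.19553
18.4939 5.07913 0.168119 0.263397 5.51064 5.06439
19.7617 4.14717 0.169042 0.238437 4.55465 4.13772
20 3.99772 0.169187 0.234165 4.40107 3.98909
21.1164 3.38432 0.169766 0.215683 3.76977 3.37902
22.564 2.76024 0.1703 0.194979 3.12552 2.75823
24.1109 2.24997 0.170652 0.176177 2.5968 2.25059
25 2.01183 0.17077 0.166664 2.34927 2.01366
25.7637 1.833 0.17083 0.159145 2.16298 1.83574
27.5299 1.49218 0.170841 0.143757 1.80677 1.49666
28 1.41561 0.170818 0.140076 1.72651 1.4205
29.4172 1.21382 0.170691 0.129892 1.5144 1.21976
30 1.14177 0.170617 0.126064 1.43845 1.14811
31.4338 0.986878 0.170388 0.117434 1.2747 0.994067
33.5887 0.801958 0.169937 0.106268 1.07816 0.810231
35.8913 0.651355 0.169346 0.0962842 0.916985 0.660592
38.3518 0.528762 0.168619 0.0873729 0.784754 0.538877
40 0.463102 0.168091 0.0822269 0.713419 0.473739
40.9809 0.429023 0.167764 0.0794314 0.676218 0.439952
43.7903 0.347919 0.166785 0.072363 0.587066 0.359617
46.7922 0.282002 0.165688 0.0660784 0.513768 0.294437
50 0.228456 0.164478 0.0604965 0.453431 0.241608
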