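# Photon mass interaction coefficients for Mg (Z=12, A=24.3050)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 836.325 0.0186868 2.14812 838.492 836.325
1.06855 699.281 0.0207899 2.12266 701.424 699.281
1.14181 584.499 0.0230741 2.09499 586.617 584.499
1.22008 488.381 0.0255406 2.0651 490.472 488.381
1.30372 407.908 0.0281877 2.03299 409.969 407.908
1.30435 407.375 0.0282075 2.03274 409.436 407.375
1.30565 5244.74 0.0282488 2.03224 5246.8 5114.2
1.39309 4908.12 0.0310102 1.99872 4910.15 4793.62
1.48859 4128.36 0.0339991 1.9624 4130.36 4038.23
1.5 4046.9 0.0343533 1.95809 4048.89 3959.22
1.59064 3471.77 0.0371419 1.92417 3473.73 3400.84
1.69969 2919.31 0.0404227 1.88423 2921.23 2863.49
1.81621 2462.56 0.0438236 1.84277 2464.45 2418.5
1.94071 2074.17 0.0473252 1.80004 2076.02 2039.44
2 1917.78 0.0489424 1.78028 1919.61 1886.62
2.07375 1744.42 0.0509086 1.75624 1746.22 1717.08
2.21592 1464.87 0.0545569 1.71158 1466.64 1443.39
2.36782 1228.27 0.0582571 1.66621 1230 1211.41
2.53015 1028.32 0.0620012 1.62022 1030.01 1015.12
2.70359 859.498 0.0657875 1.57361 861.137 849.167
2.88893 717.395 0.0696201 1.52633 718.991 709.326
3 646.956 0.0718249 1.49909 648.527 639.949
3.08698 597.769 0.0735087 1.47825 599.321 591.477
3.2986 497.25 0.0774661 1.4292 498.756 492.351
3.52473 413.248 0.081506 1.37899 414.708 409.438
3.76636 343.116 0.0856401 1.32746 344.529 340.156
4 289.584 0.0894807 1.27945 290.953 287.232
4.02456 284.619 0.0898761 1.2745 285.984 282.322
4.30045 235.874 0.0942152 1.22007 237.189 234.093
4.59526 195.294 0.0986514 1.16422 196.556 193.913
4.91028 161.542 0.103171 1.10711 162.753 160.474
5 153.36 0.104417 1.09132 154.556 152.365
5.2469 133.498 0.107753 1.04897 134.654 132.672
5.60659 110.218 0.112369 0.99011 111.32 109.58
5.99094 90.8588 0.116985 0.930935 91.9067 90.3675
6 90.4586 0.11709 0.929585 91.5053 89.9702
6.40163 74.8382 0.121566 0.871882 75.8316 74.46
6.84049 61.5974 0.12607 0.813423 62.5369 61.3067
7.30942 50.6622 0.130458 0.756037 51.5487 50.4391
7.81051 41.6378 0.134692 0.700182 42.4727 41.4669
8 38.78 0.136178 0.680449 39.5966 38.6249
8.34594 34.1958 0.138737 0.646277 34.9808 34.0652
8.397 33.5807 0.139098 0.64143 34.3613 33.4533
8.91808 28.0619 0.142564 0.594681 28.7991 27.9624
9.52944 22.9774 0.146149 0.54568 23.6692 22.902
9.672 21.9698 0.146916 0.535085 22.6518 21.8991
10 19.863 0.148592 0.511813 20.5234 19.8017
10.1827 18.804 0.149474 0.499486 19.453 18.7473
10.8808 15.3804 0.152529 0.456228 15.9891 15.3379
11.286 13.7635 0.154095 0.433652 14.3513 13.7276
11.6267 12.5732 0.155307 0.415965 13.1445 12.5418
12.4237 10.2728 0.15781 0.378687 10.8093 10.25
13.2754 8.38876 0.160041 0.34433 8.89313 8.37258
14.1855 6.8465 0.162008 0.312781 7.32129 6.83547
15 5.76757 0.163468 0.288287 6.21933 5.76
15.1579 5.58473 0.163723 0.283894 6.03235 5.57773
16.1971 4.553 0.165196 0.257499 4.9757 4.54917
17.3074 3.70985 0.166441 0.233414 4.1097 3.70853
18.4939 3.02117 0.167471 0.211451 3.40009 3.02187
19.7617 2.45899 0.168299 0.191432 2.81872 2.46133
20 2.36901 0.168428 0.188008 2.72544 2.37161
21.1164 2.00031 0.168937 0.173192 2.34244 2.00401
22.564 1.6263 0.169393 0.15658 1.95227 1.63114
24.1109 1.32149 0.169678 0.141466 1.63263 1.32732
25 1.1796 0.169763 0.133802 1.48316 1.18591
25.7637 1.07322 0.169798 0.127735 1.37075 1.07991
27.5299 0.8711 0.16976 0.115283 1.15614 0.878581
28 0.825835 0.169726 0.112298 1.10786 0.833506
29.4172 0.706702 0.169571 0.104019 0.980292 0.714907
30 0.664238 0.169487 0.1009 0.934625 0.672648
31.4338 0.573069 0.169236 0.0938541 0.836159 0.581956
33.5887 0.464494 0.168761 0.0847074 0.717962 0.474035
35.8913 0.376318 0.168149 0.0764997 0.620967 0.386495
38.3518 0.304742 0.167408 0.0691549 0.541305 0.315545
40 0.266492 0.166872 0.0649075 0.498272 0.27769
40.9809 0.246667 0.166541 0.062599 0.475807 0.258092
43.7903 0.199568 0.165554 0.0567603 0.421883 0.211615
46.7922 0.161389 0.164452 0.0515703 0.377411 0.17406
50 0.130454 0.163239 0.0469634 0.340656 0.143754
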