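# Photon mass interaction coefficients for C (Z=6, A=12.0107)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 2072.58 0.0202026 1.07892 2073.68 2072.58
1.06855 1722.33 0.0227162 1.06371 1723.42 1722.33
1.14181 1429.64 0.0254955 1.04688 1430.72 1429.64
1.22008 1184.11 0.0285561 1.02833 1185.16 1184.11
1.30372 979.925 0.0319114 1.00799 980.965 979.925
1.39309 810.278 0.0355717 0.985773 811.299 810.278
1.48859 669.444 0.0395431 0.961653 670.446 669.445
1.5 654.857 0.0400203 0.958753 655.856 654.857
1.59064 552.629 0.0438265 0.935614 553.609 552.63
1.69969 455.82 0.0484167 0.907683 456.776 455.82
1.81621 375.656 0.0533018 0.877927 376.587 375.656
1.94071 309.333 0.058462 0.846458 310.238 309.333
2 283.151 0.0608876 0.831653 284.044 283.152
2.07375 254.508 0.06387 0.813437 255.385 254.508
2.21592 209.225 0.0694907 0.77907 210.074 209.225
2.36782 171.856 0.0752819 0.743606 172.675 171.857
2.53015 141.044 0.081196 0.707329 141.833 141.045
2.70359 115.66 0.0871806 0.670551 116.418 115.661
2.88893 94.7652 0.0931811 0.633599 95.4919 94.7658
3 84.5772 0.096581 0.612623 85.2864 84.5779
3.08698 77.5604 0.0991423 0.596801 78.2563 77.5611
3.2986 63.4106 0.105011 0.56048 64.0761 63.4115
3.52473 51.8062 0.110737 0.524936 52.4418 51.8071
3.76636 42.2959 0.116276 0.490438 42.9026 42.2969
4 35.1628 0.121108 0.460228 35.7442 35.164
4.02456 34.5074 0.121588 0.45722 35.0862 34.5085
4.30045 28.1335 0.126642 0.425473 28.6856 28.1347
4.59526 22.9209 0.131414 0.395342 23.4476 22.9223
4.91028 18.6611 0.135888 0.366925 19.1639 18.6626
5 17.64 0.137056 0.35947 18.1365 17.6416
5.2469 15.1823 0.140054 0.340272 15.6626 15.184
5.60659 12.337 0.143911 0.315391 12.7963 12.3388
5.99094 10.0181 0.147463 0.29225 10.4578 10.02
6 9.9706 0.147541 0.291742 10.4099 9.97254
6.40163 8.13095 0.150721 0.270785 8.55246 8.13305
6.84049 6.59598 0.153697 0.250908 7.00059 6.59824
7.30942 5.34809 0.156409 0.232511 5.73701 5.35052
7.81051 4.33411 0.158873 0.215479 4.70846 4.33672
8 4.01641 0.159707 0.209633 4.38575 4.01909
8.34594 3.51061 0.161108 0.199691 3.87141 3.5134
8.397 3.44312 0.161303 0.198297 3.80272 3.44594
8.91808 2.84197 0.163133 0.185027 3.19013 2.84497
9.52944 2.29546 0.164964 0.171372 2.63179 2.29866
9.672 2.18818 0.16535 0.168441 2.52197 2.19144
10 1.96508 0.166183 0.162017 2.29328 1.96844
10.1827 1.85358 0.166618 0.158618 2.17882 1.85701
10.8808 1.4964 0.168108 0.146668 1.81118 1.50007
11.286 1.32964 0.168864 0.140391 1.6389 1.33345
11.6267 1.20775 0.169447 0.135438 1.51264 1.21167
12.4237 0.974546 0.170643 0.124857 1.27005 0.978725
13.2754 0.786176 0.171704 0.114871 1.07275 0.790634
14.1855 0.634061 0.172635 0.105438 0.912135 0.638815
15 0.528948 0.173321 0.0979048 0.800173 0.533963
15.1579 0.511253 0.173439 0.0965322 0.781225 0.516319
16.1971 0.412131 0.174117 0.0881362 0.674384 0.417525
17.3074 0.332145 0.174669 0.080243 0.587057 0.337885
18.4939 0.267617 0.175093 0.0728513 0.515561 0.27372
19.7617 0.215573 0.175389 0.0659626 0.456924 0.222056
20 0.207302 0.175428 0.0647711 0.447502 0.213857
21.1164 0.173607 0.175554 0.0595779 0.408739 0.180489
22.564 0.139777 0.175588 0.0536949 0.36906 0.147074
24.1109 0.112511 0.175492 0.0483055 0.336309 0.120241
25 0.0999268 0.175385 0.0455653 0.320877 0.107901
25.7637 0.0905421 0.175267 0.0433946 0.309203 0.0987225
27.5299 0.0727604 0.174914 0.0389407 0.286615 0.0814082
28 0.068785 0.174804 0.0378735 0.281462 0.0775549
29.4172 0.0583908 0.174437 0.0349168 0.267744 0.0675232
30 0.0547115 0.174272 0.0338042 0.262788 0.0639906
31.4338 0.0468623 0.173839 0.0312923 0.251994 0.0564965
33.5887 0.0376126 0.173125 0.028035 0.238772 0.0477653
35.8913 0.0301906 0.172297 0.0251127 0.2276 0.0408787
38.3518 0.0242349 0.171359 0.0224945 0.218089 0.0354746
40 0.0210812 0.170709 0.0209773 0.212768 0.0326792
40.9809 0.0194554 0.170316 0.0201512 0.209923 0.0312625
43.7903 0.0156196 0.16917 0.0180558 0.202846 0.0280094
46.7922 0.0125409 0.167924 0.0161836 0.196649 0.0255279
50 0.0100697 0.166582 0.014512 0.191164 0.0236674
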