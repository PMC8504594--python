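# Photon mass interaction coefficients for Na (Z=11, A=22.9898)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 596.961 0.0169778 1.9208 598.898 596.961
1.06855 499.092 0.0187898 1.9007 501.012 499.092
1.07156 495.31 0.0188697 1.89981 497.229 495.31
1.07264 5584.49 0.0188981 1.89949 5586.41 5479.19
1.14181 6510.77 0.0207363 1.87908 6512.67 6395.45
1.22008 5459.6 0.0228156 1.85597 5461.47 5369.1
1.30372 4580.17 0.0250245 1.83141 4582.03 4509.12
1.39309 3844.34 0.0273584 1.80543 3846.18 3788.53
1.48859 3246.02 0.0298122 1.77809 3247.82 3201.92
1.5 3183.13 0.0301021 1.77486 3184.93 3140.21
1.59064 2736.87 0.0323809 1.74945 2738.65 2702.07
1.69969 2304.16 0.0350605 1.71953 2305.91 2276.74
1.81621 1936.96 0.0378494 1.68836 1938.69 1915.39
1.94071 1625.85 0.0407488 1.65592 1627.55 1608.91
2 1500.91 0.0421023 1.64076 1502.6 1485.74
2.07375 1362.67 0.0437638 1.62213 1364.33 1349.38
2.21592 1139.92 0.0469035 1.5869 1141.56 1129.52
2.36782 952.023 0.0501802 1.55007 953.623 943.892
2.53015 794.171 0.0536088 1.51147 795.736 787.823
2.70359 661.722 0.0572046 1.47092 663.25 656.772
2.88893 550.719 0.0609817 1.42824 552.209 546.865
3 495.83 0.063216 1.40296 497.296 492.488
3.08698 457.619 0.064951 1.3833 459.068 454.622
3.2986 379.686 0.0691179 1.33603 381.091 377.358
3.52473 314.739 0.0734817 1.2864 316.099 312.934
3.76636 260.667 0.0780339 1.23451 261.979 259.268
4 219.501 0.0823155 1.18557 220.769 218.392
4.02456 215.688 0.0827582 1.1805 216.951 214.605
4.30045 178.309 0.0876303 1.12465 179.521 177.471
4.59526 147.273 0.0926182 1.06727 148.433 146.626
4.91028 121.442 0.0976831 1.0088 122.549 120.943
5 115.193 0.0990739 0.992705 116.285 114.728
5.2469 100.054 0.102781 0.949712 101.106 99.6696
5.60659 82.373 0.107864 0.890528 83.3714 82.0773
5.99094 67.7674 0.112882 0.831788 68.7121 67.5402
6 67.466 0.112996 0.830458 68.4094 67.2401
6.40163 55.7111 0.117789 0.774024 56.6029 55.5368
6.84049 45.7664 0.122538 0.717733 46.6067 45.633
7.30942 37.5696 0.127091 0.663354 38.36 37.4677
7.81051 30.8183 0.131414 0.611252 31.561 30.7408
8 28.6833 0.132916 0.593034 29.4092 28.6132
8.34594 25.2618 0.135483 0.561714 25.959 25.2031
8.397 24.8031 0.135843 0.557293 25.4963 24.7459
8.91808 20.6911 0.139277 0.51494 21.3453 20.6469
9.52944 16.9127 0.142787 0.471056 17.5266 16.8798
9.672 16.1648 0.143533 0.461631 16.77 16.134
10 14.602 0.145155 0.441004 15.1881 14.5756
10.1827 13.8169 0.146005 0.430118 14.3931 13.7927
10.8808 11.2818 0.148933 0.392124 11.8229 11.2643
11.286 10.0863 0.150424 0.372413 10.6092 10.0718
11.6267 9.20698 0.151573 0.357022 9.71557 9.19466
12.4237 7.50971 0.153934 0.324719 7.98836 7.50144
13.2754 6.12206 0.156023 0.29509 6.57317 6.11697
14.1855 4.98815 0.157855 0.267984 5.41399 4.98558
15 4.19618 0.159207 0.246992 4.60238 4.19532
15.1579 4.06209 0.159442 0.243231 4.46477 4.06151
16.1971 3.30619 0.160798 0.22065 3.68764 3.30722
17.3074 2.68951 0.161938 0.200058 3.05151 2.69186
18.4939 2.18669 0.162876 0.181281 2.53085 2.19013
19.7617 1.77692 0.163623 0.164153 2.1047 1.7813
20 1.71141 0.163739 0.161222 2.03637 1.71594
21.1164 1.44317 0.164191 0.148529 1.75589 1.44836
22.564 1.17147 0.16459 0.134279 1.47034 1.17739
24.1109 0.95034 0.164828 0.121292 1.23646 0.956921
25 0.847574 0.164892 0.114696 1.12716 0.854498
25.7637 0.770614 0.164911 0.109468 1.04499 0.777814
27.5299 0.624629 0.164846 0.098722 0.888196 0.63242
28 0.591973 0.164806 0.0961411 0.85292 0.599912
29.4172 0.506087 0.164638 0.0889747 0.759699 0.51445
30 0.475496 0.16455 0.0862716 0.726317 0.484027
31.4338 0.409864 0.164293 0.0801544 0.654311 0.418791
33.5887 0.331793 0.163815 0.0721934 0.567801 0.34128
35.8913 0.268477 0.163209 0.0650277 0.496713 0.278524
38.3518 0.217149 0.162479 0.0585958 0.438223 0.22776
40 0.189749 0.161953 0.0548673 0.40657 0.200723
40.9809 0.175557 0.16163 0.052838 0.390025 0.18674
43.7903 0.14187 0.160666 0.0476968 0.350233 0.153633
46.7922 0.114598 0.159591 0.0431164 0.317305 0.126948
50 0.0925274 0.15841 0.0390436 0.289981 0.105474
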