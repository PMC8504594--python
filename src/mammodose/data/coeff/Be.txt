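# Photon mass interaction coefficients for Be (Z=4, A=9.0122)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 548.867 0.0297621 0.591568 549.488 548.867
1.06855 451.16 0.0330687 0.578225 451.771 451.16
1.14181 370.535 0.0366292 0.563848 371.135 370.535
1.22008 304.063 0.0404379 0.548458 304.652 304.064
1.30372 249.308 0.0444831 0.532101 249.884 249.308
1.39309 204.241 0.0487467 0.514845 204.805 204.241
1.48859 167.181 0.0532044 0.496788 167.731 167.181
1.5 163.363 0.0537286 0.494663 163.912 163.363
1.59064 136.731 0.0578255 0.47805 137.267 136.731
1.69969 111.733 0.0625736 0.458776 112.255 111.734
1.81621 91.2294 0.0674082 0.439126 91.7359 91.2297
1.94071 74.4256 0.0722853 0.419277 74.9172 74.426
2 67.8387 0.0745005 0.410251 68.3235 67.8391
2.07375 60.6663 0.0771595 0.399409 61.1429 60.6667
2.21592 49.388 0.0819862 0.379701 49.8497 49.3885
2.36782 40.1793 0.0867222 0.360325 40.6263 40.1798
2.53015 32.6668 0.0913287 0.341437 33.0996 32.6674
2.70359 26.5421 0.0957714 0.323175 26.9611 26.5427
2.88893 21.552 0.100023 0.305649 21.9577 21.5527
3 19.1384 0.102348 0.29604 19.5368 19.1391
3.08698 17.473 0.104061 0.288944 17.866 17.4737
3.2986 14.1425 0.107874 0.273113 14.5235 14.1433
3.52473 11.4426 0.111455 0.258176 11.8122 11.4435
3.76636 9.25481 0.114807 0.244124 9.61374 9.25579
4 7.63044 0.117658 0.232103 7.9802 7.63149
4.02456 7.48199 0.117938 0.230918 7.83085 7.48305
4.30045 6.04651 0.120864 0.218494 6.38587 6.04766
4.59526 4.88473 0.123603 0.20677 5.21511 4.88597
4.91028 3.94481 0.126178 0.195655 4.26664 3.94615
5 3.72095 0.126856 0.192714 4.04052 3.72232
5.2469 3.18464 0.12861 0.185059 3.49831 3.18609
5.60659 2.57006 0.130918 0.174896 2.87588 2.57162
5.99094 2.07337 0.133119 0.165092 2.37158 2.07505
6 2.06323 0.133168 0.164872 2.36127 2.06492
6.40163 1.67208 0.135227 0.155588 1.9629 1.67389
6.84049 1.348 0.137251 0.146338 1.63159 1.34994
7.30942 1.08635 0.139197 0.137312 1.36286 1.08844
7.81051 0.87518 0.141068 0.128491 1.14474 0.877436
8 0.809324 0.141727 0.125352 1.0764 0.81164
8.34594 0.704816 0.142865 0.119872 0.967552 0.707242
8.397 0.690906 0.143026 0.119089 0.953022 0.693349
8.91808 0.567393 0.144583 0.111462 0.823438 0.570002
9.52944 0.456029 0.146218 0.103278 0.705525 0.458833
9.672 0.434242 0.146572 0.101479 0.682292 0.437091
10 0.389014 0.147349 0.0974864 0.63385 0.391968
10.1827 0.366458 0.147761 0.0953479 0.609567 0.369469
10.8808 0.294427 0.149204 0.0877043 0.531335 0.297658
11.286 0.260932 0.149953 0.0836245 0.49451 0.264291
11.6267 0.236512 0.150537 0.0803825 0.467431 0.239976
12.4237 0.189955 0.151751 0.0734168 0.415123 0.193665
13.2754 0.152536 0.152838 0.0668371 0.372211 0.156505
14.1855 0.122466 0.153791 0.0606661 0.336923 0.126707
15 0.10178 0.154488 0.0557971 0.312064 0.10626
15.1579 0.098306 0.154607 0.0549172 0.30783 0.102832
16.1971 0.0788984 0.155284 0.0495941 0.283776 0.0837228
17.3074 0.063311 0.155822 0.0446913 0.263824 0.068447
18.4939 0.050794 0.156222 0.0401957 0.247212 0.0562553
19.7617 0.0407445 0.156489 0.0360888 0.233322 0.046545
20 0.0391519 0.156523 0.0353862 0.231061 0.0450153
21.1164 0.0326774 0.156626 0.0323487 0.221652 0.0388315
22.564 0.0262029 0.156637 0.0289518 0.211792 0.032725
24.1109 0.0210075 0.156526 0.0258742 0.203408 0.0279124
25 0.0186176 0.156416 0.0243198 0.199354 0.025738
25.7637 0.0168392 0.156299 0.0230926 0.196231 0.0241421
27.5299 0.0134859 0.155958 0.020584 0.190028 0.0212018
28 0.0127398 0.155853 0.0199845 0.188577 0.0205637
29.4172 0.0107921 0.155507 0.0183263 0.184625 0.0189364
30 0.0101038 0.155353 0.0177032 0.18316 0.0183778
31.4338 0.00863776 0.154951 0.0162981 0.179887 0.0172258
33.5887 0.00691464 0.154292 0.0144793 0.175686 0.0159617
35.8913 0.00553616 0.153534 0.0128506 0.171921 0.0150572
38.3518 0.00443323 0.15268 0.0113943 0.168508 0.0144431
40 0.00385056 0.15209 0.010552 0.166493 0.0141781
40.9809 0.0035506 0.151734 0.010094 0.165378 0.0140636
43.7903 0.00284417 0.150696 0.00893451 0.162475 0.0138741
46.7922 0.00227867 0.149571 0.00790203 0.159752 0.0138386
50 0.0018259 0.148361 0.00698386 0.157171 0.013928
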