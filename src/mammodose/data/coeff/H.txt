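# Photon mass interaction coefficients for H (Z=1, A=1.0079)
# Generated by tools/make_coefficient_tables.py; see that script for the physics sources.
# columns: energy_keV photoelectric incoherent coherent total energy_absorption   [cm^2/g]
1 1e-12 0.0385809 0.358675 0.397256 0.000104102
1.06855 1e-12 0.0434898 0.353723 0.397213 0.000125172
1.14181 1e-12 0.0489445 0.348218 0.397163 0.00015023
1.22008 1e-12 0.0549846 0.342119 0.397103 0.000179937
1.30372 1e-12 0.061647 0.335386 0.397033 0.00021503
1.39309 1e-12 0.0689639 0.327985 0.396949 0.000256321
1.48859 1e-12 0.0769614 0.319891 0.396852 0.000304695
1.5 1e-12 0.0779265 0.318913 0.39684 0.00031076
1.59064 1e-12 0.0856565 0.311082 0.396738 0.000361096
1.69969 1e-12 0.095055 0.301551 0.396606 0.000426514
1.81621 1e-12 0.10515 0.291305 0.396454 0.000501963
1.94071 1e-12 0.115917 0.280363 0.39628 0.00058845
2 1e-12 0.121015 0.275178 0.396193 0.000631607
2.07375 1e-12 0.127316 0.268765 0.396081 0.000686945
2.21592 1e-12 0.139286 0.25657 0.395856 0.000798342
2.36782 1e-12 0.151749 0.243854 0.395603 0.000923416
2.53015 1e-12 0.164606 0.230714 0.395321 0.00106279
2.70359 1e-12 0.177744 0.217265 0.395008 0.00121689
2.88893 1e-12 0.191034 0.203631 0.394665 0.00138596
3 1e-12 0.198612 0.195845 0.394457 0.00148883
3.08698 1e-12 0.204341 0.189951 0.394292 0.00156998
3.2986 1e-12 0.217525 0.176363 0.393888 0.00176878
3.52473 1e-12 0.23045 0.163004 0.393454 0.00198197
3.76636 1e-12 0.242987 0.150004 0.392991 0.00220907
4 1e-12 0.253935 0.138611 0.392547 0.00242677
4.02456 1e-12 0.255023 0.137478 0.3925 0.00244951
4.30045 1e-12 0.266462 0.12552 0.391983 0.00270275
4.59526 1e-12 0.277232 0.114207 0.391439 0.00296834
4.91028 1e-12 0.287279 0.10359 0.390869 0.00324596
5 1e-12 0.289893 0.100816 0.390709 0.00332384
5.2469 1e-12 0.296575 0.093699 0.390274 0.0035355
5.60659 1e-12 0.305107 0.0845447 0.389652 0.00383707
5.99094 1e-12 0.312883 0.0761199 0.389003 0.00415103
6 1e-12 0.313052 0.0759362 0.388988 0.00415834
6.40163 1e-12 0.319922 0.0684035 0.388326 0.00447797
6.84049 1e-12 0.326254 0.0613642 0.387618 0.00481869
7.30942 1e-12 0.331914 0.0549635 0.386877 0.00517421
7.81051 1e-12 0.336942 0.0491587 0.386101 0.00554568
8 1e-12 0.338612 0.0471982 0.385811 0.00568415
8.34594 1e-12 0.34138 0.0439057 0.385285 0.00593438
8.397 1e-12 0.34176 0.0434486 0.385208 0.00597104
8.91808 1e-12 0.345267 0.0391608 0.384428 0.00634164
9.52944 1e-12 0.348643 0.0348823 0.383525 0.00676884
9.672 1e-12 0.349332 0.0339839 0.383316 0.00686739
10 1e-12 0.350796 0.0320422 0.382838 0.00709269
10.1827 1e-12 0.351543 0.0310307 0.382573 0.00721737
10.8808 1e-12 0.354 0.0275695 0.381569 0.00768857
11.286 1e-12 0.355176 0.0258152 0.380992 0.00795863
11.6267 1e-12 0.356044 0.0244645 0.380509 0.00818381
12.4237 1e-12 0.357705 0.0216842 0.379389 0.0087044
13.2754 1e-12 0.359007 0.0191989 0.378206 0.00925162
14.1855 1e-12 0.359974 0.016981 0.376955 0.00982673
15 1e-12 0.360546 0.015302 0.375848 0.0103335
15.1579 1e-12 0.360629 0.0150049 0.375634 0.010431
16.1971 1e-12 0.360991 0.013247 0.374238 0.0110654
17.3074 1e-12 0.361078 0.0116855 0.372764 0.0117313
18.4939 1e-12 0.360907 0.0103002 0.371207 0.0124295
19.7617 1e-12 0.360491 0.00907295 0.369564 0.0131609
20 1e-12 0.36039 0.00886664 0.369257 0.0132968
21.1164 1e-12 0.359843 0.00798692 0.36783 0.0139266
22.564 1e-12 0.358976 0.00702693 0.366003 0.014727
24.1109 1e-12 0.357898 0.00617921 0.364078 0.0155628
25 1e-12 0.357224 0.00575912 0.362984 0.0160345
25.7637 1e-12 0.35662 0.00543132 0.362051 0.0164345
27.5299 1e-12 0.355147 0.00477203 0.359919 0.0173423
28 1e-12 0.354741 0.00461665 0.359357 0.0175799
29.4172 1e-12 0.353487 0.0041913 0.357678 0.0182863
30 1e-12 0.352961 0.00403318 0.356994 0.0185725
31.4338 1e-12 0.351646 0.00368009 0.355326 0.0192663
33.5887 1e-12 0.349627 0.00323036 0.352858 0.0202821
35.8913 1e-12 0.347437 0.00283492 0.350272 0.0213329
38.3518 1e-12 0.345077 0.00248738 0.347565 0.0224181
40 1e-12 0.343494 0.00228906 0.345783 0.0231241
40.9809 1e-12 0.342553 0.00218207 0.344735 0.0235364
43.7903 1e-12 0.339865 0.00191395 0.341779 0.0246865
46.7922 1e-12 0.337018 0.00167857 0.338697 0.0258667
50 1e-12 0.334014 0.001472 0.335486 0.0270749
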