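element,energy_keV,mu_over_rho_cm2_g
H,10,0.3854
H,15,0.3764
H,20,0.3695
H,30,0.357
H,40,0.3458
H,50,0.3355
H,60,0.326
H,80,0.3091
H,100,0.2944
H,150,0.2651
H,200,0.2429
H,300,0.2112
H,400,0.1893
H,500,0.1729
C,10,2.373
C,15,0.8071
C,20,0.442
C,30,0.2562
C,40,0.2076
C,50,0.1871
C,60,0.1753
C,80,0.161
C,100,0.1514
C,150,0.1347
C,200,0.1229
C,300,0.1066
C,400,0.09546
C,500,0.08715
N,10,3.879
N,15,1.236
N,20,0.6178
N,30,0.3066
N,40,0.2288
N,50,0.198
N,60,0.1817
N,80,0.1639
N,100,0.1529
N,150,0.1353
N,200,0.1233
N,300,0.1068
N,400,0.09557
N,500,0.08719
O,10,5.952
O,15,1.836
O,20,0.8651
O,30,0.3779
O,40,0.2585
O,50,0.2132
O,60,0.1907
O,80,0.1678
O,100,0.1551
O,150,0.1361
O,200,0.1237
O,300,0.107
O,400,0.09566
O,500,0.08729
Na,10,15.42
Na,15,4.694
Na,20,2.057
Na,30,0.7197
Na,40,0.3969
Na,50,0.2804
Na,60,0.2268
Na,80,0.1796
Na,100,0.1585
Na,150,0.1335
Na,200,0.1199
Na,300,0.1029
Na,400,0.09185
Na,500,0.08372
Mg,10,20.99
Mg,15,6.358
Mg,20,2.763
Mg,30,0.9306
Mg,40,0.4881
Mg,50,0.3292
Mg,60,0.257
Mg,80,0.1951
Mg,100,0.1686
Mg,150,0.1394
Mg,200,0.1245
Mg,300,0.1065
Mg,400,0.09492
Mg,500,0.08647
Al,10,26.23
Al,15,7.955
Al,20,3.441
Al,30,1.128
Al,40,0.5685
Al,50,0.3681
Al,60,0.2778
Al,80,0.2018
Al,100,0.1704
Al,150,0.1378
Al,200,0.1223
Al,300,0.1042
Al,400,0.09276
Al,500,0.08445
P,10,40.27
P,15,12.05
P,20,5.358
P,30,1.7
P,40,0.8096
P,50,0.4916
P,60,0.3494
P,80,0.2324
P,100,0.1865
P,150,0.1432
P,200,0.125
P,300,0.1044
P,400,0.09232
P,500,0.08382
S,10,50.12
S,15,15.1
S,20,6.708
S,30,2.113
S,40,0.9872
S,50,0.5849
S,60,0.4053
S,80,0.2585
S,100,0.202
S,150,0.1506
S,200,0.1302
S,300,0.1081
S,400,0.09522
S,500,0.08619
Cl,10,59.0
Cl,15,15.8
Cl,20,6.5
Cl,30,2.03
Cl,40,0.917
Cl,50,0.566
Cl,60,0.4
Cl,80,0.259
Cl,100,0.2019
Cl,150,0.1484
Cl,200,0.1267
Cl,300,0.1056
Cl,400,0.09326
Cl,500,0.08458
Ca,10,93.41
Ca,15,30.3
Ca,20,12.4
Ca,30,4.08
Ca,40,1.83
Ca,50,1.019
Ca,60,0.6578
Ca,80,0.3656
Ca,100,0.257
Ca,150,0.1666
Ca,200,0.1376
Ca,300,0.111
Ca,400,0.0965
Ca,500,0.0876
Fe,10,170.6
Fe,15,57.08
Fe,20,25.68
Fe,30,8.176
Fe,40,3.629
Fe,50,1.958
Fe,60,1.205
Fe,80,0.5952
Fe,100,0.3717
Fe,150,0.1964
Fe,200,0.146
Fe,300,0.1099
Fe,400,0.094
Fe,500,0.08414
Cu,10,215.9
Cu,15,74.05
Cu,20,33.79
Cu,30,10.92
Cu,40,4.862
Cu,50,2.613
Cu,60,1.593
Cu,80,0.763
Cu,100,0.4584
Cu,150,0.2217
Cu,200,0.1559
Cu,300,0.1119
Cu,400,0.09413
Cu,500,0.08362
Ga,10,31.0
Ga,10.3,28.5
Ga,10.45,230.0
Ga,15,90.6
Ga,20,41.3
Ga,30,13.4
Ga,40,5.97
Ga,50,3.22
Ga,60,1.97
Ga,80,0.94
Ga,100,0.526
Ga,150,0.24
Ga,200,0.163
Ga,300,0.1125
Ga,400,0.0933
Ga,500,0.0823
Mo,10,85.8
Mo,15,27.9
Mo,19.95,12.2
Mo,20.05,77.5
Mo,30,26.9
Mo,40,12.1
Mo,50,5.92
Mo,60,3.5
Mo,80,1.51
Mo,100,1.0
Mo,150,0.387
Mo,200,0.24
Mo,300,0.144
Mo,400,0.11
Mo,500,0.092
Gd,10,135.0
Gd,15,43.5
Gd,20,19.6
Gd,30,6.1
Gd,40,2.6
Gd,50.2,1.41
Gd,50.3,7.05
Gd,60,4.51
Gd,80,2.06
Gd,100,1.103
Gd,150,0.483
Gd,200,0.287
Gd,300,0.154
Gd,400,0.112
Gd,500,0.092
Lu,10,115.0
Lu,15,62.0
Lu,20,27.8
Lu,30,8.7
Lu,40,3.7
Lu,50,1.98
Lu,63.25,1.15
Lu,63.4,10.05
Lu,80,5.75
Lu,100,3.09
Lu,150,1.13
Lu,200,0.59
Lu,300,0.272
Lu,400,0.175
Lu,500,0.131
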