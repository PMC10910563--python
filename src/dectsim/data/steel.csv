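energy_kev,mu_over_rho
1.0,9085.0
1.5,3399.0
2.0,1626.0
3.0,557.6
4.0,256.7
5.0,139.8
6.0,84.84
8.0,305.6
10.0,170.6
15.0,57.08
20.0,25.68
30.0,8.176
40.0,3.629
50.0,1.958
60.0,1.205
80.0,0.5952
100.0,0.3717
150.0,0.1964
200.0,0.1460
300.0,0.1099
400.0,0.09400
500.0,0.08414
600.0,0.07704
800.0,0.06699
1000.0,0.05995
1250.0,0.05350
1500.0,0.04883
2000.0,0.04265
3000.0,0.03621
4000.0,0.03312
5000.0,0.03146
6000.0,0.03057
8000.0,0.02991
10000.0,0.02994
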