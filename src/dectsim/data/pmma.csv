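energy_kev,mu_over_rho
1.0,2794.0
1.5,915.3
2.0,403.7
3.0,123.6
4.0,52.47
5.0,26.81
6.0,15.45
8.0,6.494
10.0,3.357
15.0,1.101
20.0,0.5714
30.0,0.3032
40.0,0.2350
50.0,0.2074
60.0,0.1924
80.0,0.1751
100.0,0.1641
150.0,0.1456
200.0,0.1328
300.0,0.1152
400.0,0.1031
500.0,0.09410
600.0,0.08701
800.0,0.07641
1000.0,0.06870
1250.0,0.06143
1500.0,0.05591
2000.0,0.04796
3000.0,0.03844
4000.0,0.03286
5000.0,0.02919
6000.0,0.02659
8000.0,0.02323
10000.0,0.02116
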