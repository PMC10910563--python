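energy_kev,mu_over_rho
1.0,1185.0
1.5,402.2
2.0,2263.0
3.0,788.0
4.0,360.5
5.0,193.4
6.0,115.3
8.0,50.33
10.0,26.23
15.0,7.955
20.0,3.441
30.0,1.128
40.0,0.5685
50.0,0.3681
60.0,0.2778
80.0,0.2018
100.0,0.1704
150.0,0.1378
200.0,0.1223
300.0,0.1042
400.0,0.09276
500.0,0.08445
600.0,0.07802
800.0,0.06841
1000.0,0.06146
1250.0,0.05496
1500.0,0.05006
2000.0,0.04324
3000.0,0.03541
4000.0,0.03106
5000.0,0.02836
6000.0,0.02655
8000.0,0.02437
10000.0,0.02318
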