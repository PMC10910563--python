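energy_kev,mu_over_rho
1.0,4070.0
1.5,1385.0
2.0,624.0
3.0,195.8
4.0,84.20
5.0,43.30
6.0,25.10
8.0,10.55
10.0,5.367
15.0,1.688
20.0,0.8206
30.0,0.3785
40.0,0.2698
50.0,0.2274
60.0,0.2061
80.0,0.1837
100.0,0.1705
150.0,0.1502
200.0,0.1367
300.0,0.1183
400.0,0.1058
500.0,0.09663
600.0,0.08934
800.0,0.07846
1000.0,0.07054
1250.0,0.06307
1500.0,0.05739
2000.0,0.04930
3000.0,0.03962
4000.0,0.03400
5000.0,0.03031
6000.0,0.02772
8000.0,0.02436
10000.0,0.02231
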