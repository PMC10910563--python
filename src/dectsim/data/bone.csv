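energy_kev,mu_over_rho
1.0,3500.0
1.5,1250.0
2.0,560.0
3.0,230.0
4.0,255.0
5.0,190.0
6.0,117.0
8.0,53.00
10.0,28.51
15.0,9.032
20.0,4.001
30.0,1.331
40.0,0.6655
50.0,0.4242
60.0,0.3148
80.0,0.2229
100.0,0.1855
150.0,0.1480
200.0,0.1309
300.0,0.1113
400.0,0.09908
500.0,0.09022
600.0,0.08332
800.0,0.07308
1000.0,0.06566
1250.0,0.05871
1500.0,0.05346
2000.0,0.04607
3000.0,0.03745
4000.0,0.03257
5000.0,0.02946
6000.0,0.02734
8000.0,0.02467
10000.0,0.02314
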