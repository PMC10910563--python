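energy_kev,mu_over_rho,muen_over_rho
1.0,4078.0,4065.0
1.5,1376.0,1372.0
2.0,617.3,615.2
3.0,192.9,191.7
4.0,82.78,81.91
5.0,42.58,41.88
6.0,24.64,24.05
8.0,10.37,9.915
10.0,5.329,4.944
15.0,1.673,1.374
20.0,0.8096,0.5503
30.0,0.3756,0.1557
40.0,0.2683,0.06947
50.0,0.2269,0.04223
60.0,0.2059,0.03190
80.0,0.1837,0.02597
100.0,0.1707,0.02546
150.0,0.1505,0.02764
200.0,0.1370,0.02967
300.0,0.1186,0.03192
400.0,0.1061,0.03279
500.0,0.09687,0.03299
600.0,0.08956,0.03284
800.0,0.07865,0.03206
1000.0,0.07072,0.03103
1250.0,0.06323,0.02965
1500.0,0.05754,0.02833
2000.0,0.04942,0.02608
3000.0,0.03969,0.02281
4000.0,0.03403,0.02066
5000.0,0.03031,0.01915
6000.0,0.02770,0.01806
8000.0,0.02429,0.01658
10000.0,0.02219,0.01566
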