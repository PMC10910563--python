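energy_kev,mu_over_rho
1.0,5869.0
1.5,2096.0
2.0,986.8
3.0,332.3
4.0,151.7
5.0,683.8
6.0,432.3
8.0,202.3
10.0,110.7
15.0,35.87
20.0,15.85
30.0,4.972
40.0,2.214
50.0,1.213
60.0,0.7661
80.0,0.4052
100.0,0.2721
150.0,0.1649
200.0,0.1314
300.0,0.1043
400.0,0.09081
500.0,0.08191
600.0,0.07529
800.0,0.06572
1000.0,0.05891
1250.0,0.05263
1500.0,0.04801
2000.0,0.04180
3000.0,0.03512
4000.0,0.03173
5000.0,0.02982
6000.0,0.02868
8000.0,0.02759
10000.0,0.02727
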