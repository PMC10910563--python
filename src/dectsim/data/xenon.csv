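energy_kev,mu_over_rho
1.0,9000.0
1.5,3500.0
2.0,1800.0
3.0,700.0
4.0,350.0
5.0,700.0
6.0,450.0
8.0,220.0
10.0,125.0
15.0,43.00
20.0,20.50
30.0,6.900
40.0,21.00
50.0,11.70
60.0,7.250
80.0,3.330
100.0,1.830
150.0,0.6600
200.0,0.3520
300.0,0.1710
400.0,0.1180
500.0,0.09500
600.0,0.08220
800.0,0.06800
1000.0,0.05920
1250.0,0.05210
1500.0,0.04770
2000.0,0.04250
3000.0,0.03820
4000.0,0.03660
5000.0,0.03600
6000.0,0.03580
8000.0,0.03620
10000.0,0.03700
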