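# material: Si (Z=14), density 2.33 g/cm3
# columns: energy_keV, mu_rho_cm2_g (total mass attenuation), muen_rho_cm2_g (mass energy-absorption)
# abridged transcription of a standard mass-attenuation compilation on its native grid (2-100 keV);
# grid starts above the Si K edge (1.839 keV); energy-absorption column approximate above 30 keV
energy_keV,mu_rho_cm2_g,muen_rho_cm2_g
2.0,2777.0,2669.0
3.0,978.4,945.7
4.0,452.9,438.1
5.0,245.0,236.7
6.0,147.0,141.6
8.0,64.68,61.75
10.0,33.89,32.10
15.0,10.34,9.594
20.0,4.464,4.076
30.0,1.436,1.219
40.0,0.7012,0.5511
50.0,0.4385,0.2350
60.0,0.3207,0.1540
80.0,0.2228,0.0780
100.0,0.1835,0.0511
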