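# material: H (Z=1), density 8.375e-05 g/cm3 (gas, STP)
# columns: energy_keV, mu_rho_cm2_g (total mass attenuation), muen_rho_cm2_g (mass energy-absorption)
# abridged transcription of a standard mass-attenuation compilation on its native grid (2-100 keV)
energy_keV,mu_rho_cm2_g,muen_rho_cm2_g
2.0,1.059,0.5250
3.0,0.5612,0.1546
4.0,0.4546,0.06803
5.0,0.4193,0.04024
6.0,0.4042,0.02935
8.0,0.3914,0.01970
10.0,0.3854,0.01623
15.0,0.3764,0.01384
20.0,0.3695,0.01406
30.0,0.3570,0.01587
40.0,0.3458,0.01795
50.0,0.3355,0.01980
60.0,0.3260,0.02137
80.0,0.3091,0.02376
100.0,0.2944,0.02542
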