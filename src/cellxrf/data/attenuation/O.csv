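# material: O (Z=8), density 1.332e-03 g/cm3 (gas, STP)
# columns: energy_keV, mu_rho_cm2_g (total mass attenuation), muen_rho_cm2_g (mass energy-absorption)
# abridged transcription of a standard mass-attenuation compilation on its native grid (2-100 keV);
# values consistent with the compilation's liquid-water row through the H2O mixture rule
energy_keV,mu_rho_cm2_g,muen_rho_cm2_g
2.0,694.95,692.65
3.0,217.13,215.84
4.0,93.15,92.22
5.0,47.89,47.15
6.0,27.69,27.08
8.0,11.63,11.162
10.0,5.9519,5.5649
15.0,1.8363,1.5454
20.0,0.8650,0.6178
30.0,0.3779,0.17333
40.0,0.2585,0.07596
50.0,0.2132,0.04506
60.0,0.1907,0.033228
80.0,0.1679,0.026248
100.0,0.1551,0.025465
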