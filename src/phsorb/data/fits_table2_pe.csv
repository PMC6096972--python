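compound,log_kow,kp_n_report,kp_i_report,cv_ph4,cv_ph7,cv_ph10
Atrazine,2.61,<5e+01,<5e+01,49.3,60.1,54.7
Benzotriazole,1.44,<5e+01,<5e+01,185.3,69.2,38.8
Caffeine,0.07,<5e+01,n.a.,69.4,63.1,157.0
Carbamazepine,2.45,6.7e+01,<5e+01,129.2,59.3,60.6
Carbendazim,1.52,<5e+01,<5e+01,161.8,54.2,57.3
DEET,2.18,5.2e+01,n.a.,122.0,44.3,100.8
Diazinon,3.81,1.75e+03,<5e+01,39.0,75.8,14.7
Diclofenac,4.51,1.5e+02,<5e+01,57.9,61.6,133.6
Ibuprofen,3.97,2.6e+02,1.9e+02,35.5,59.4,81.0
MCPA,3.25,8.8e+03,<5e+01,74.2,163.3,13130.3
Mecoprop,3.20,<5e+01,<5e+01,146.7,522.4,139.9
4-Nonylphenol,5.76,6.0e+03,7.2e+02,13.5,13.6,12.4
Phenanthrene,4.46,9.9e+03,n.a.,8.7,12.4,28.3
Propiconazole,3.72,3.4e+02,<5e+01,45.0,52.0,26.2
TCPP,2.59,2.2e+02,n.a.,77.5,84.8,24.6
Tebuconazole,3.70,1.4e+02,<5e+01,48.0,75.0,35.4
Terbutryn,3.74,6.2e+01,6.3e+01,31.8,53.8,18.1
Torasemide,3.37,1.3e+02,<5e+01,210.6,34.1,34.0
Triclosan,4.76,1.1e+03,<5e+01,27.8,38.2,203.1
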