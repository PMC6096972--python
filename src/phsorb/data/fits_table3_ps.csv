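compound,log_kow,kp_n_report,kp_i_report,cv_ph4,cv_ph7,cv_ph10
Atrazine,2.61,<5e+01,<5e+01,244.2,335.9,257.3
Benzotriazole,1.44,<5e+01,<5e+01,444.7,88.4,213.7
Caffeine,0.07,<5e+01,n.a.,1785.7,428.3,1199.7
Carbamazepine,2.45,<5e+01,<5e+01,172.2,175.6,283.2
Carbendazim,1.52,<5e+01,<5e+01,471.1,598.5,117.5
DEET,2.18,<5e+01,n.a.,177.1,240.7,500.2
Diazinon,3.81,2.15e+03,2.09e+03,93.6,82.5,53.5
Diclofenac,4.51,2.70e+02,<5e+01,93.0,214.2,6101.7
Ibuprofen,3.97,2.05e+02,<5e+01,45.9,184.0,161.0
MCPA,3.25,<5e+01,<5e+01,699.7,1564.9,196.7
Mecoprop,3.20,<5e+01,<5e+01,138.6,609.1,2206.8
4-Nonylphenol,5.76,9.18e+03,3.74e+03,18.7,49.8,31.2
Phenanthrene,4.46,7.21e+03,n.a.,29.8,21.5,40.4
Propiconazole,3.72,1.17e+02,<5e+01,44.5,169.0,48.9
TCPP,2.59,1.06e+02,n.a.,42.5,61.5,30.6
Tebuconazole,3.70,9.89e+01,<5e+01,57.3,97.0,85.7
Terbutryn,3.74,<5e+01,<5e+01,158.7,166.8,90.2
Torasemide,3.37,<5e+01,<5e+01,2502.6,95.4,70.5
Triclosan,4.76,5.12e+03,<5e+01,95.6,123.4,241.9
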