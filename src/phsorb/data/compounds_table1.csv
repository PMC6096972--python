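name,cas,mw_g_per_mol,log_kow,pka,ion_class,ws_sub_mol_per_L
Atrazine,1912-24-9,215.69,2.61,1.60,base,5.43e-3
Benzotriazole,95-14-7,119.13,1.44,8.37,base,1.05
Caffeine,58-08-2,194.19,0.07,,neutral,1.65e1
Carbamazepine,298-46-4,236.28,2.45,13.9,acid,3.10e-3
Carbendazim,10605-21-7,191.19,1.52,4.29,base,9.27e-2
DEET,134-62-3,191.28,2.18,,neutral,
Diazinon,333-41-5,304.35,3.81,2.60,base,1.31e-3
Diclofenac,15307-86-5,296.15,4.51,3.99,acid,1.87e-4
Ibuprofen,15687-27-1,206.29,3.97,4.45,acid,3.69e-4
MCPA,94-74-6,200.62,3.25,3.13,acid,3.13e-2
Mecoprop,7085-19-0,214.65,3.20,3.78,acid,1.62e-2
4-Nonylphenol,104-40-5,220.36,5.76,10.7,acid,4.78e-5
Phenanthrene,85-01-8,178.24,4.46,,neutral,3.95e-5
Propiconazole,60207-90-1,342.22,3.72,1.09,base,
TCPP,13674-84-5,327.57,2.59,,neutral,
Tebuconazole,107534-96-3,307.83,3.70,1.76,base,7.78e-4
Terbutryn,886-50-0,241.36,3.74,4.30,base,7.15e-4
Torasemide,56211-40-6,348.42,3.37,6.68,acid,2.10e-2
Triclosan,3380-34-5,289.55,4.76,7.90,acid,7.55e-5
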