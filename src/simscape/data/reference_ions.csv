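mz,annotation,ion_class,mean_LEAN,mean_P1,mean_P2,log2fc_lean_p1,log2fc_p2_p1,trend,q
536.376,PI frag. (phosphatidylinositol),lipid,3.9e-5,1.8e-5,2.1e-5,1.16,0.24,Up,1.07e-8
241.043,FA frag. (palmitoleic acid),lipid,1.28e-3,9.06e-4,9.24e-4,0.50,0.03,Up,1.55e-5
221.059,Myristic acid frag.,lipid,3.56e-4,5.65e-4,5.30e-4,-0.66,-0.09,Down,7.08e-6
281.253,Oleic/linoleic acid [M-H]-,lipid,2.8e-3,9.6e-3,1.37e-2,-1.75,0.52,Mixed,2.6e-3
283.270,Stearic acid [M-H]-,lipid,4.35e-3,4.21e-3,4.82e-3,0.05,0.20,Up,8.2e-3
404.288,Phospholipid frag.,lipid,4.32e-5,4.15e-5,5.08e-5,0.06,0.29,Up,1.3e-2
115.011,Aspartic acid,lipid,3.18e-4,5.18e-4,4.70e-4,-0.71,-0.14,Down,9.4e-4
465.318,Phosphatidic acid frag.,lipid,9.14e-5,1.36e-4,1.06e-4,-0.57,-0.35,Down,6.3e-3
805.749,PS/PI molecular ion,lipid,2.97e-6,5.89e-6,1.87e-5,-0.99,1.67,Mixed,2.5e-3
806.840,PS/PI adduct,lipid,3.29e-6,5.00e-6,1.24e-5,-0.61,1.31,Mixed,2.6e-3
180.05,Tyrosine [M-H]-,amino_acid,1.45e-3,7.81e-4,8.54e-4,0.890,0.128,Up,3.56e-6
164.07,Phenylalanine [M-H]-,amino_acid,4.30e-3,3.09e-3,3.37e-3,0.476,0.124,Up,6.87e-6
93.05,Small acidic frag.,amino_acid,7.40e-4,1.07e-3,9.13e-4,-0.532,-0.228,Down,2.99e-3
114.03,Acidic AA frag.,amino_acid,9.73e-4,1.60e-3,1.41e-3,-0.717,-0.180,Down,2.67e-3
153.02,AA frag. (aromatic/amide),amino_acid,2.89e-4,3.23e-4,3.79e-4,-0.161,0.232,Mixed,2.67e-3
128.07,Amino acid-related ion,amino_acid,2.46e-3,2.24e-3,1.83e-3,0.136,-0.294,Mixed,4.82e-3
89.03,Lactate [M-H]-,amino_acid,2.38e-3,3.99e-3,3.67e-3,-0.746,-0.120,Down,4.41e-3
209.03,Amino acid/peptidic fragment,amino_acid,1.83e-3,1.70e-3,1.34e-3,0.113,-0.345,Mixed,1.06e-2
40.01,Small frag. (C/O),amino_acid,5.29e-4,5.85e-4,6.59e-4,-0.145,0.172,Mixed,1.18e-2
86.03,AA frag.,amino_acid,2.36e-3,2.89e-3,2.90e-3,-0.293,0.0057,Mixed,1.20e-2
87.01,AA frag.,amino_acid,1.17e-3,1.31e-3,1.41e-3,-0.164,0.107,Mixed,2.50e-2
122.01,Anion (AA/acid),amino_acid,5.33e-4,7.34e-4,6.57e-4,-0.462,-0.159,Down,2.37e-2
42.00,Small fragment,amino_acid,9.74e-3,1.16e-2,1.23e-2,-0.253,0.0871,Mixed,2.74e-2
44.02,Small fragment,amino_acid,5.46e-4,5.71e-4,6.79e-4,-0.0661,0.250,Mixed,1.64e-2
65.01,Amino frag. (amine),amino_acid,4.52e-2,3.90e-2,3.86e-2,0.214,-0.0151,Mixed,1.64e-2
49.01,Small anion,amino_acid,6.27e-4,7.57e-4,5.90e-4,-0.271,-0.359,Down,4.70e-2
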