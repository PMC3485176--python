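# Default operating point of the synthetic bacteria-yeast ecosystem.
# Units: first-order rates 1/h; Gc and receptor pools M; cmax cells;
# volumes L; alpha1/alpha2 1/molecule; noise_scale dimensionless.
k1: 0.234
k2: 0.936
cmax: 1.0e+9
k3: 4.0e+6
Gc: 3.0e-7
alpha1: 5.0e+4
alpha2: 5.0e+4
k4: 5.0e-6
k5: 5.0e-6
k6: 3.0e+19
k9: 3.0e+19
AHLR1_conc: 5.0e-7
AHLR2_conc: 5.0e-7
k7: 6.0e-5
k7b: 1.0e-8
n1: 1.0
k10: 6.0e-5
k10b: 1.0e-8
n2: 1.0
k8: 5.0
k11: 1.19
k12: 1.19
k13: 1.386
k14: 1.386
k15: 4.0
k16: 4.0
V1: 3.7e-14
V2: 1.0e-15
Na: 6.023e+23
d: 0.0
noise_scale: 1.0
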