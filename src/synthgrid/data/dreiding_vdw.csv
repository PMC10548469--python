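# Dreiding-style 12-6 van der Waals parameters.
# type, D0 (kcal/mol), R0 (Angstrom)
H_,0.0152,3.1950
H__HB,0.0001,3.1950
B_3,0.0950,4.0200
C_3,0.0951,3.8983
C_2,0.0951,3.8983
C_R,0.0951,3.8983
C_1,0.0951,3.8983
N_3,0.0774,3.6621
N_2,0.0774,3.6621
N_R,0.0774,3.6621
N_1,0.0774,3.6621
O_3,0.0957,3.4046
O_2,0.0957,3.4046
O_R,0.0957,3.4046
F_,0.0725,3.4720
P_3,0.3200,4.1500
S_3,0.3440,4.0300
Cl_,0.2833,3.9503
Br_,0.3700,4.3300
I_,0.5100,4.5100
Na_,0.5000,3.1440
K_,0.5000,4.1870
Ca_,0.0500,3.8000
Mg_,0.0500,3.2000
Zn_,0.0550,4.5400
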