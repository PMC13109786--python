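# gppi default amino-acid property table, version 1
# hydropathy: Kyte & Doolittle (1982) hydropathy index
# vdw_volume: van der Waals residue volume, A^3 (Darby & Creighton 1993)
# polarizability: Charton & Charton (1982) polarizability parameter
# pka_carboxyl / pka_amino / pka_side: standard free-amino-acid pKa values; NA = no ionizable side chain
code	hydropathy	vdw_volume	polarizability	pka_carboxyl	pka_amino	pka_side
A	1.8	67.0	0.046	2.34	9.69	NA
R	-4.5	148.0	0.291	2.17	9.04	12.48
N	-3.5	96.0	0.134	2.02	8.80	NA
D	-3.5	91.0	0.105	1.88	9.60	3.65
C	2.5	86.0	0.128	1.96	10.28	8.18
Q	-3.5	114.0	0.180	2.17	9.13	NA
E	-3.5	109.0	0.151	2.19	9.67	4.25
G	-0.4	48.0	0.000	2.34	9.60	NA
H	-3.2	118.0	0.230	1.82	9.17	6.00
I	4.5	124.0	0.186	2.36	9.68	NA
L	3.8	124.0	0.186	2.36	9.60	NA
K	-3.9	135.0	0.219	2.18	8.95	10.53
M	1.9	124.0	0.221	2.28	9.21	NA
F	2.8	135.0	0.290	1.83	9.13	NA
P	-1.6	90.0	0.131	1.99	10.96	NA
S	-0.8	73.0	0.062	2.21	9.15	NA
T	-0.7	93.0	0.108	2.11	9.62	NA
W	-0.9	163.0	0.409	2.38	9.39	NA
Y	-1.3	141.0	0.298	2.20	9.11	10.07
V	4.2	105.0	0.140	2.32	9.62	NA
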