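# aggscape propensity scales, version 1
# hydrophobicity: Kyte-Doolittle; beta/alpha: Chou-Fasman conformational
# propensities; charge: formal side-chain charge at pH 7.4 (His fractional).
aa	hydrophobicity	beta	alpha	charge
A	1.8	0.83	1.42	0.0
R	-4.5	0.93	0.98	1.0
N	-3.5	0.89	0.67	0.0
D	-3.5	0.54	1.01	-1.0
C	2.5	1.19	0.70	0.0
Q	-3.5	1.10	1.11	0.0
E	-3.5	0.37	1.51	-1.0
G	-0.4	0.75	0.57	0.0
H	-3.2	0.87	1.00	0.1
I	4.5	1.60	1.08	0.0
L	3.8	1.30	1.21	0.0
K	-3.9	0.74	1.16	1.0
M	1.9	1.05	1.45	0.0
F	2.8	1.38	1.13	0.0
P	-1.6	0.55	0.57	0.0
S	-0.8	0.75	0.77	0.0
T	-0.7	1.19	0.83	0.0
W	-0.9	1.37	1.08	0.0
Y	-1.3	1.47	0.69	0.0
V	4.2	1.70	1.06	0.0
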