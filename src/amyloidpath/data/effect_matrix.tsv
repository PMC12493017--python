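res	1	2	3	4	5	6
A	-0.26	-0.32	-0.27	-0.14	-0.43	-0.22
R	-0.45	-0.41	-0.46	-0.33	-0.52	-0.35
N	-0.40	-0.34	-0.49	-0.27	-0.46	-0.30
D	-0.49	-0.43	-0.56	-0.41	-0.56	-0.36
C	-0.09	-0.21	0.03	-0.05	-0.17	-0.05
Q	-0.37	-0.30	-0.36	-0.34	-0.48	-0.32
E	-0.51	-0.41	-0.43	-0.30	-0.61	-0.39
G	-0.23	-0.37	-0.46	-0.37	-0.30	-0.33
H	-0.32	-0.26	-0.26	-0.30	-0.35	-0.25
I	-0.06	-0.08	0.26	0.09	-0.06	-0.07
L	-0.10	-0.18	0.02	0.04	-0.22	-0.13
K	-0.39	-0.45	-0.51	-0.35	-0.59	-0.32
M	-0.17	-0.25	-0.02	-0.10	-0.19	-0.18
F	-0.13	-0.11	0.05	-0.03	-0.13	-0.11
P	-0.56	-0.38	-0.56	-0.51	-0.42	-0.45
S	-0.37	-0.35	-0.41	-0.30	-0.48	-0.23
T	-0.34	-0.33	-0.28	-0.23	-0.40	-0.23
W	-0.17	-0.17	-0.09	-0.06	-0.12	-0.16
Y	-0.23	-0.11	-0.13	-0.06	-0.18	-0.15
V	-0.05	-0.14	0.19	0.14	-0.19	0.01
__intercept__	1.083	1.083	1.083	1.083	1.083	1.083
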