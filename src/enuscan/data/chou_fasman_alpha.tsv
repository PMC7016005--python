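# Chou & Fasman (1978) alpha-helix propensity P-alpha
aa	palpha
A	1.42
C	0.70
D	1.01
E	1.51
F	1.13
G	0.57
H	1.00
I	1.08
K	1.16
L	1.21
M	1.45
N	0.67
P	0.57
Q	1.11
R	0.98
S	0.77
T	0.83
V	1.06
W	1.08
Y	0.69
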