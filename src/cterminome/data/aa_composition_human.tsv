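residue	frequency
A	0.082591
R	0.055361
N	0.040645
D	0.054560
C	0.013715
Q	0.039343
E	0.067574
G	0.070778
H	0.022725
I	0.059666
L	0.096706
K	0.058464
M	0.024227
F	0.038643
P	0.047052
S	0.065672
T	0.053459
W	0.010812
Y	0.029232
V	0.068776
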