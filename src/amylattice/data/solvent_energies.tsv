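# Default residue-solvent contact energies (reduced units per exposed contact).
# Hydrophobic residues pay +0.9 * s_i / s_F for solvent exposure (positive,
# required for burial-driven assembly); polar and charged residues are 0.
# With alpha = 60 the exposure of a hydrophobic side chain becomes favourable
# below T0 - sqrt(0.9/60) = 0.28, the model's cold-denaturation region.
A	0.1559
C	0.7743
D	0.0000
E	0.0000
F	0.9000
G	0.0000
H	0.0000
I	0.9050
K	0.0000
L	0.8547
M	0.6184
N	0.0000
P	0.0000
Q	0.0000
R	0.0000
S	0.0000
T	0.0000
V	0.6134
W	1.1313
Y	0.4827
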