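# Default residue-residue side-chain contact energies (reduced k_B T units,
# per directed side-chain contact: a side chain pointing at a residue of
# another molecule, or a non-adjacent residue of its own chain, contributes
# eps[a_i, a_j]; a mutually buried pair therefore counts twice).
# eps_ij = -1.35 * (s_i * s_j) / s_F^2 for hydrophobic pairs, 0 otherwise,
# with s_i the Fauchere-Pliska octanol-water side-chain hydrophobicity.
# Calibrated jointly with the solvent vector and eps_hb so that eps_FF <
# eps_LL < 0 and the TFTFTFT fibril is stable over an intermediate
# temperature window at alpha = 0, with cold denaturation into monomers
# near T = 0.225-0.25 at alpha = 60.
# Rows/columns in the order ACDEFGHIKLMNPQRSTVWY.
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.0405	-0.2011	0.0000	0.0000	-0.2338	0.0000	0.0000	-0.2351	0.0000	-0.2220	-0.1607	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.1593	-0.2939	-0.1254
C	-0.2011	-0.9992	0.0000	0.0000	-1.1615	0.0000	0.0000	-1.1679	0.0000	-1.1031	-0.7981	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.7916	-1.4599	-0.6229
D	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
E	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
F	-0.2338	-1.1615	0.0000	0.0000	-1.3500	0.0000	0.0000	-1.3575	0.0000	-1.2821	-0.9277	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.9201	-1.6969	-0.7240
G	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
H	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
I	-0.2351	-1.1679	0.0000	0.0000	-1.3575	0.0000	0.0000	-1.3651	0.0000	-1.2893	-0.9328	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.9253	-1.7064	-0.7281
K	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
L	-0.2220	-1.1031	0.0000	0.0000	-1.2821	0.0000	0.0000	-1.2893	0.0000	-1.2177	-0.8810	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.8738	-1.6116	-0.6876
M	-0.1607	-0.7981	0.0000	0.0000	-0.9277	0.0000	0.0000	-0.9328	0.0000	-0.8810	-0.6374	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.6323	-1.1660	-0.4975
N	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
P	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
Q	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
R	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
S	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
T	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
V	-0.1593	-0.7916	0.0000	0.0000	-0.9201	0.0000	0.0000	-0.9253	0.0000	-0.8738	-0.6323	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.6271	-1.1566	-0.4935
W	-0.2939	-1.4599	0.0000	0.0000	-1.6969	0.0000	0.0000	-1.7064	0.0000	-1.6116	-1.1660	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-1.1566	-2.1330	-0.9101
Y	-0.1254	-0.6229	0.0000	0.0000	-0.7240	0.0000	0.0000	-0.7281	0.0000	-0.6876	-0.4975	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.4935	-0.9101	-0.3883
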