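# Default model parameters (reduced units, k_B = 1).
# eps_hb: energy per hydrogen bond (favourable < 0); exceeds the beta-state
# penalty ln(n_beta) so strand formation is net favourable by 0.4 per bond
eps_hb = -1.4
# n_beta: multiplicity of non-strand states; E_state = ln(n_beta) per beta residue
n_beta = 2.718281828459045
# steric_penalty: energy per side-chain crowding event (two side chains
# pointing at the same site, or a side chain pointing at its backbone neighbour)
steric_penalty = 2.0
# alpha: strength of the hydrophobic temperature dependence (0 disables it)
alpha = 0.0
# t0: temperature of the maximal hydrophobic effect
t0 = 0.4
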