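"""The five-term Hamiltonian, its temperature split, and the compiled kernel."""

import numpy as np
import pytest

from amylattice import mc
from amylattice import _kernels as K
from amylattice.hamiltonian import (
    InteractionTables,
    default_tables,
    hb_energy,
    load_model_params,
    load_pair_matrix,
    load_solvent_vector,
    pair_energy,
    phi_solvent,
    state_energy,
    steric_energy,
    total_energy,
)
from amylattice.lattice import (
    Conformation,
    LatticeSystem,
    Sequence,
    build_seed,
    reference_fibrillar_state,
    reference_monomeric_state,
)
from amylattice.thermo import HydrophobicParams

from conftest import toy_tables


def single_monomer(sequence="TFTFTFT", box=12):
    """One extended chain, side chains pointing +z into solvent."""
    seq = Sequence(sequence)
    n = len(seq)
    pos = np.stack([np.arange(2, 2 + n), np.full(n, 5), np.full(n, 5)], axis=1)
    chain = Conformation(pos, np.full(n, 4), np.zeros(n, dtype=bool))
    return LatticeSystem(sequence=seq, chains=[chain], n_seed=0, box=box)


def two_stacked_strands(aligned=True, beta=True):
    """Two in-register strands stacked along z, side chains along +y (or
    anti-aligned), the hydrogen-bonding geometry of a beta-sheet."""
    seq = Sequence("TFTFTFT")
    n = len(seq)
    chains = []
    for k in (0, 1):
        pos = np.stack([np.arange(2, 2 + n), np.full(n, 5), np.full(n, 5 + k)], axis=1)
        sdir = np.full(n, 2 if (aligned or k == 0) else 3)
        chains.append(Conformation(pos, sdir, np.full(n, beta, dtype=bool)))
    return LatticeSystem(sequence=seq, chains=chains, n_seed=0, box=12)


class TestPhiSolvent:
    def test_no_exposure_means_zero(self, fibrillar, hp60):
        tab = toy_tables()
        # fibrillar reference: hydrophobics buried, polar solvent energy zero
        assert phi_solvent(fibrillar, tab, hp60, 0.25) == pytest.approx(0.0, abs=1e-5)

    def test_extended_monomer_alpha_zero(self):
        tab = toy_tables(eps_f_solv=1.0)
        sys1 = single_monomer()
        val = phi_solvent(sys1, tab, HydrophobicParams(0.0, 0.4), 0.25)
        assert val == pytest.approx(3.0, abs=1e-5)  # 3 exposed F x 1.0

    def test_extended_monomer_with_hydrophobic_term(self):
        tab = toy_tables(eps_f_solv=1.0)
        sys1 = single_monomer()
        val = phi_solvent(sys1, tab, HydrophobicParams(60.0, 0.4), 0.25)
        assert val == pytest.approx(3 * (1.0 - 1.35), abs=1e-5)

    def test_rejects_nonpositive_temperature(self, fibrillar, tables, hp0):
        with pytest.raises(ValueError):
            phi_solvent(fibrillar, tables, hp0, 0.0)


class TestHBondEnergy:
    def test_stacked_aligned_strands_bond_once_per_residue(self):
        tab = toy_tables(eps_hb=-1.0)
        assert hb_energy(two_stacked_strands(aligned=True), tab) == pytest.approx(-7.0)

    def test_anti_aligned_side_chains_do_not_bond(self):
        tab = toy_tables(eps_hb=-1.0)
        assert hb_energy(two_stacked_strands(aligned=False), tab) == 0.0

    def test_non_beta_residues_do_not_bond(self):
        tab = toy_tables(eps_hb=-1.0)
        assert hb_energy(two_stacked_strands(beta=False), tab) == 0.0

    def test_separated_strands_have_no_bonds(self, tables):
        sys2 = two_stacked_strands()
        # pull the strands far apart: no unit-distance partners remain
        sys2.chains[1].positions = sys2.chains[1].positions + np.array([0, 0, 4])
        assert hb_energy(sys2, toy_tables()) == 0.0


class TestStateEnergy:
    def test_counts_beta_residues(self):
        tab = toy_tables(n_beta=np.e)
        sys2 = two_stacked_strands()
        assert state_energy(sys2, tab) == pytest.approx(14.0)  # ln(e) per residue

    def test_no_penalty_for_n_beta_one(self, fibrillar):
        tab = toy_tables(n_beta=1.0)
        assert state_energy(fibrillar, tab) == 0.0


class TestPairEnergy:
    def test_docked_layer_has_six_directed_ff_contacts(self, fibrillar):
        """Each free chain's 3 F side chains point at the partner's F
        backbone: 6 directed F-F contacts in the docked layer, plus 12 in the
        4-layer seed."""
        tab = toy_tables(eps_ff=-1.0)
        mono_val = pair_energy(reference_monomeric_state(fibrillar), tab)
        fib_val = pair_energy(fibrillar, tab)
        assert fib_val - mono_val == pytest.approx(-6.0)

    def test_monomeric_reference_is_zero_beyond_seed(self, monomeric):
        tab = toy_tables(eps_ff=-1.0)
        # the frozen seed's own core contributes a constant
        seed_core = 2 * 3 * 4  # 2 directed contacts x 3 F pairs x 4 layers
        assert pair_energy(monomeric, tab) == pytest.approx(-seed_core)

    def test_exposed_side_chains_make_no_pair_energy(self):
        tab = toy_tables(eps_ff=-1.0)
        assert pair_energy(single_monomer(), tab) == 0.0


def test_steric_penalises_backbone_neighbour_pointing():
    tab = toy_tables(steric=2.0)
    sys1 = single_monomer()
    # point one side chain at its backbone neighbour
    sys1.chains[0].side_dirs[3] = 0  # +x, the next residue's site
    assert steric_energy(sys1, tab) == pytest.approx(2.0)


def test_steric_penalises_shared_target_site():
    seq = Sequence("FF")
    # two chains whose side chains point at the same empty site
    c1 = Conformation(np.array([[2, 2, 2], [3, 2, 2]]), np.array([2, 4]), np.zeros(2, bool))
    c2 = Conformation(np.array([[2, 4, 2], [3, 4, 2]]), np.array([3, 4]), np.zeros(2, bool))
    sys2 = LatticeSystem(sequence=seq, chains=[c1, c2], n_seed=0, box=8)
    # c1 residue 0 points +y at (2,3,2); c2 residue 0 points -y at (2,3,2)
    tab = toy_tables(steric=2.0)
    assert steric_energy(sys2, tab) == pytest.approx(2.0)


class TestTotalEnergy:
    def test_breakdown_sums_to_total(self, fibrillar, tables, hp60):
        b = total_energy(fibrillar, tables, hp60, 0.3)
        assert b.total == pytest.approx(
            b.e_hb + b.e_steric + b.e_state + b.e_aa + b.phi_solvent
        )
        assert b.e_int == pytest.approx(b.total - b.phi_solvent)

    def test_temperature_enters_only_through_phi(self, monomeric, tables, hp60):
        b1 = total_energy(monomeric, tables, hp60, 0.2)
        b2 = total_energy(monomeric, tables, hp60, 0.35)
        assert b1.total - b2.total == pytest.approx(b1.phi_solvent - b2.phi_solvent)
        assert b1.e_int == pytest.approx(b2.e_int)

    def test_enthalpy_estimate_equals_total_at_alpha_zero(self, monomeric, tables, hp0):
        b = total_energy(monomeric, tables, hp0, 0.3)
        assert b.enthalpy_estimate == pytest.approx(b.total)

    def test_enthalpy_estimate_uses_gibbs_helmholtz(self, monomeric, tables, hp60):
        b = total_energy(monomeric, tables, hp60, 0.2)
        # 6 exposed F: replace F_hydr (-alpha (t-t0)^2) by E_hydr (-alpha (t0^2-t^2))
        assert b.enthalpy_estimate - b.total == pytest.approx(
            6 * (-60 * (0.16 - 0.04)) - 6 * (-60 * 0.04)
        )


def test_kernel_matches_reference_on_random_trajectories(tables):
    """The compiled energy kernel must agree term-by-term with the plain
    reference implementation along an actual Monte Carlo trajectory."""
    hp = HydrophobicParams(60.0, 0.4)
    system = build_seed("TFTFTFT")
    state = mc.pack_system(reference_fibrillar_state(system), tables, hp, 0.3)
    cfg = mc.MCConfig(temperatures=(0.3,), sweeps=2, equilibration_sweeps=0)
    rng = np.array([2468, 1357], dtype=np.uint64)
    att = np.zeros(10, dtype=np.int64)
    acc = np.zeros(10, dtype=np.int64)
    for _ in range(100):
        state.run(60, rng, cfg.cumulative_move_weights(), att, acc)
        b = total_energy(mc.unpack_system(state), tables, hp, 0.3)
        assert b.total == pytest.approx(float(state.comp[K.TOTAL]), abs=1e-9)
        assert b.e_aa == pytest.approx(float(state.comp[K.E_AA]), abs=1e-9)
        assert b.e_hb == pytest.approx(float(state.comp[K.E_HB]), abs=1e-9)
        assert b.e_steric == pytest.approx(float(state.comp[K.E_STERIC]), abs=1e-9)
        assert b.phi_solvent == pytest.approx(
            float(state.comp[K.E_SOLV] + state.comp[K.F_HYDR]), abs=1e-9
        )


def test_parameter_files_round_trip(tmp_path, tables):
    from amylattice.hamiltonian import _data_path

    pair = load_pair_matrix(_data_path("pair_energies.tsv"))
    assert np.allclose(pair, pair.T)
    solv = load_solvent_vector(_data_path("solvent_energies.tsv"))
    assert np.all(solv >= 0)
    params = load_model_params(_data_path("default_model.params"))
    assert set(params) >= {"eps_hb", "n_beta", "steric_penalty", "alpha", "t0"}
    bad = tmp_path / "bad.params"
    bad.write_text("eps_hb -1\n")
    with pytest.raises(ValueError, match="key = value"):
        load_model_params(bad)


def test_table_invariants_enforced():
    pair = np.zeros((20, 20))
    pair[0, 1] = 1.0  # asymmetric
    with pytest.raises(ValueError, match="symmetric"):
        InteractionTables(pair_energies=pair, solvent_energies=np.ones(20))
    with pytest.raises(ValueError, match="positive solvent"):
        InteractionTables(pair_energies=np.zeros((20, 20)), solvent_energies=np.zeros(20))
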