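import numpy as np
import pytest

from amylattice.hamiltonian import InteractionTables, default_tables
from amylattice.lattice import (
    AA_ALPHABET,
    build_seed,
    reference_fibrillar_state,
    reference_monomeric_state,
)
from amylattice.thermo import HydrophobicParams


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture(scope="session")
def system():
    return build_seed("TFTFTFT")


@pytest.fixture(scope="session")
def fibrillar(system):
    return reference_fibrillar_state(system)


@pytest.fixture(scope="session")
def monomeric(system):
    return reference_monomeric_state(system)


@pytest.fixture
def hp0():
    return HydrophobicParams(alpha=0.0, t0=0.4)


@pytest.fixture
def hp60():
    return HydrophobicParams(alpha=60.0, t0=0.4)


def toy_tables(eps_ff=-1.0, eps_f_solv=1.0, eps_hb=-1.0, n_beta=np.e, steric=2.0):
    """Small hand-set tables for oracle tests: eps only between F-F side-chain
    contacts, solvent energy only for F (other hydrophobics kept minimally
    positive to satisfy the table invariant)."""
    pair = np.zeros((20, 20))
    i_f = AA_ALPHABET.index("F")
    pair[i_f, i_f] = eps_ff
    solv = np.zeros(20)
    for aa in "CFLWVIMYA":
        solv[AA_ALPHABET.index(aa)] = 1e-6
    solv[i_f] = eps_f_solv
    return InteractionTables(
        pair_energies=pair,
        solvent_energies=solv,
        hb_strength=eps_hb,
        beta_propensity=n_beta,
        steric_penalty=steric,
    )
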