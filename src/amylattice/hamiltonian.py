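"""The lattice Hamiltonian and its five-term decomposition.

    H = E_hb + E_steric + E_state + E_aa + Phi_solvent(T)

Only the solvation term depends on temperature, so the Hamiltonian splits as
``H = E_int + Phi_solvent(T)`` with a configuration-dependent but
temperature-independent ``E_int``.  This module is the readable reference
implementation (plain Python over the :class:`~amylattice.lattice.LatticeSystem`
containers); the Monte Carlo engine uses an equivalent compiled kernel and is
tested against this one.

Because ``Phi_solvent`` is a free energy (a potential of mean force over the
solvent), the physical enthalpy of a configuration is *not* ``H`` when
``alpha != 0``: it is obtained by replacing each exposed hydrophobic
``F_hydr`` with the Gibbs-Helmholtz enthalpy ``E_hydr`` (see
:mod:`amylattice.thermo`).  :attr:`EnergyBreakdown.enthalpy_estimate` carries
that estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .lattice import (
    AA_ALPHABET,
    AA_INDEX,
    DIRECTIONS,
    HYDROPHOBIC_RESIDUES,
    POSITIVE_DIRS,
    LatticeSystem,
)
from .thermo import HydrophobicParams

__all__ = [
    "InteractionTables",
    "EnergyBreakdown",
    "default_tables",
    "load_pair_matrix",
    "load_solvent_vector",
    "load_model_params",
    "phi_solvent",
    "hb_energy",
    "state_energy",
    "pair_energy",
    "steric_energy",
    "total_energy",
]


@dataclass(frozen=True)
class InteractionTables:
    """Interaction parameters of the lattice model (reduced units).

    ``pair_energies`` is the symmetric 20x20 residue-residue contact table in
    :data:`~amylattice.lattice.AA_ALPHABET` order; ``solvent_energies`` the
    per-residue temperature-independent solvent contact energies (positive
    for hydrophobic residues); ``hb_strength`` the energy per hydrogen bond;
    ``beta_propensity`` N_beta >= 1, the multiplicity of non-strand states a
    residue gives up in the beta state (``E_state = ln N_beta`` per beta
    residue); ``steric_penalty`` the energy per pair of side chains pointing
    at the same lattice site.
    """

    pair_energies: np.ndarray
    solvent_energies: np.ndarray
    hb_strength: float = -1.0
    beta_propensity: float = float(np.e)
    steric_penalty: float = 2.0

    def __post_init__(self) -> None:
        pe = np.asarray(self.pair_energies, dtype=float)
        sv = np.asarray(self.solvent_energies, dtype=float)
        if pe.shape != (20, 20):
            raise ValueError("pair_energies must be 20x20")
        if not np.allclose(pe, pe.T):
            raise ValueError("pair_energies must be symmetric")
        if sv.shape != (20,):
            raise ValueError("solvent_energies must have 20 entries")
        for aa in HYDROPHOBIC_RESIDUES:
            if sv[AA_INDEX[aa]] <= 0:
                raise ValueError(
                    f"hydrophobic residue {aa} must have a positive solvent energy"
                )
        if self.beta_propensity < 1:
            raise ValueError("beta_propensity must be >= 1")
        object.__setattr__(self, "pair_energies", pe)
        object.__setattr__(self, "solvent_energies", sv)


@dataclass(frozen=True)
class EnergyBreakdown:
    """The five Hamiltonian terms plus derived bookkeeping quantities.

    ``total = e_hb + e_steric + e_state + e_aa + phi_solvent`` and
    ``e_int = total - phi_solvent`` (temperature independent).
    ``enthalpy_estimate`` replaces the free-energy solvation of each exposed
    hydrophobic contact by its Gibbs-Helmholtz enthalpy; at ``alpha = 0`` it
    equals ``total``.
    """

    e_hb: float
    e_steric: float
    e_state: float
    e_aa: float
    phi_solvent: float
    e_solv_exposed: float  # temperature-independent part of phi
    e_hydr_exposed: float  # sum of per-contact E_hydr over exposed hydrophobics
    c_h_exposed: int

    @property
    def total(self) -> float:
        return self.e_hb + self.e_steric + self.e_state + self.e_aa + self.phi_solvent

    @property
    def e_int(self) -> float:
        return self.total - self.phi_solvent

    @property
    def enthalpy_estimate(self) -> float:
        return self.e_int + self.e_solv_exposed + self.e_hydr_exposed


def _read_table_lines(path_or_text: str | Path):
    text = Path(path_or_text).read_text()
    return [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]


def load_pair_matrix(path: str | Path) -> np.ndarray:
    """Read a whitespace-delimited 20x20 matrix file with residue labels."""
    lines = _read_table_lines(path)
    header = lines[0].split()
    if "".join(header) != AA_ALPHABET:
        raise ValueError(f"pair matrix columns must be {AA_ALPHABET}")
    out = np.zeros((20, 20))
    for line in lines[1:]:
        parts = line.split()
        i = AA_INDEX[parts[0]]
        out[i] = [float(v) for v in parts[1:]]
    return out


def load_solvent_vector(path: str | Path) -> np.ndarray:
    """Read a 20-entry residue/value file."""
    out = np.zeros(20)
    seen = set()
    for line in _read_table_lines(path):
        aa, val = line.split()
        out[AA_INDEX[aa]] = float(val)
        seen.add(aa)
    if len(seen) != 20:
        raise ValueError(f"solvent vector must cover all 20 residues, got {len(seen)}")
    return out


def load_model_params(path: str | Path) -> dict:
    """Read a flat key = value parameter file (``#`` comments allowed)."""
    out = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = float(val)
    return out


def _data_path(name: str) -> Path:
    return Path(resources.files("amylattice").joinpath("data").joinpath(name))


def default_tables(**overrides) -> InteractionTables:
    """The calibrated default parameterisation shipped with the package."""
    params = load_model_params(_data_path("default_model.params"))
    kwargs = dict(
        pair_energies=load_pair_matrix(_data_path("pair_energies.tsv")),
        solvent_energies=load_solvent_vector(_data_path("solvent_energies.tsv")),
        hb_strength=params["eps_hb"],
        beta_propensity=params["n_beta"],
        steric_penalty=params["steric_penalty"],
    )
    kwargs.update(overrides)
    return InteractionTables(**kwargs)


def default_hydrophobic_params(alpha: float | None = None) -> HydrophobicParams:
    params = load_model_params(_data_path("default_model.params"))
    return HydrophobicParams(
        alpha=params["alpha"] if alpha is None else alpha, t0=params["t0"]
    )


# ---------------------------------------------------------------------------
# Energy terms
# ---------------------------------------------------------------------------


def _exposure(system: LatticeSystem):
    """Per-residue solvent contact indicator K_i,solv over all chains."""
    occ = system.occupancy()
    ks = []
    for chain in system.chains:
        targets = chain.positions + DIRECTIONS[chain.side_dirs]
        ks.extend(tuple(t) not in occ for t in targets)
    return np.array(ks, dtype=bool)


def phi_solvent(
    system: LatticeSystem,
    tables: InteractionTables,
    hparams: HydrophobicParams,
    t: float,
) -> float:
    """Temperature-dependent solvation term: sum over solvent-exposed side
    chains of ``F_hydr + eps_solv`` (F_hydr only for hydrophobic residues)."""
    if t <= 0:
        raise ValueError("temperature must be > 0")
    k_solv = _exposure(system)
    codes = np.tile(system.sequence.codes, len(system.chains))
    hyd = np.tile(system.sequence.hydrophobic_flags, len(system.chains))
    f_per_contact = -hparams.alpha * (t - hparams.t0) ** 2
    return float(
        np.sum(k_solv * (tables.solvent_energies[codes] + hyd * f_per_contact))
    )


def hb_energy(system: LatticeSystem, tables: InteractionTables) -> float:
    """Hydrogen bonds between strands: unordered pairs on different molecules
    at unit distance, both in the beta state, with identical side-chain
    directions perpendicular to the pair's separation vector."""
    occ = system.occupancy()
    n = system.n_res
    pos = system.all_positions()
    sdirs = np.concatenate([c.side_dirs for c in system.chains])
    beta = np.concatenate([c.beta_flags for c in system.chains])
    count = 0
    for g, p in enumerate(pos):
        for di in POSITIVE_DIRS:
            q = tuple(p + DIRECTIONS[di])
            if q in occ:
                h = occ[q]
                if (
                    g // n != h // n
                    and beta[g]
                    and beta[h]
                    and sdirs[g] == sdirs[h]
                    and np.dot(DIRECTIONS[sdirs[g]], DIRECTIONS[di]) == 0
                ):
                    count += 1
    return tables.hb_strength * count


def state_energy(system: LatticeSystem, tables: InteractionTables) -> float:
    """Chain-entropy penalty ``ln(N_beta)`` per residue in the beta state."""
    n_beta_res = int(sum(c.beta_flags.sum() for c in system.chains))
    return float(np.log(tables.beta_propensity)) * n_beta_res


def pair_energy(system: LatticeSystem, tables: InteractionTables) -> float:
    """Side-chain-mediated residue interaction energies.

    Each side chain interacts with the occupant of the site it points at:
    solvent (handled by :func:`phi_solvent`) or a residue of another molecule
    / a non-adjacent residue of the same chain, contributing
    ``eps[a_i, a_j]``.  The sum is directed (two side chains pointing at each
    other's backbone count twice), so a fully buried mutual hydrophobic
    contact is worth ``2*eps``."""
    occ = system.occupancy()
    n = system.n_res
    codes = np.tile(system.sequence.codes, len(system.chains))
    total = 0.0
    g = 0
    for chain in system.chains:
        targets = chain.positions + DIRECTIONS[chain.side_dirs]
        for tgt in targets:
            h = occ.get(tuple(tgt))
            if h is not None and (g // n != h // n or abs(g - h) > 1):
                total += tables.pair_energies[codes[g], codes[h]]
            g += 1
    return float(total)


def steric_energy(system: LatticeSystem, tables: InteractionTables) -> float:
    """Side-chain crowding (backbone overlap is a hard constraint handled by
    move rejection, not an energy).

    Two contributions, each ``steric_penalty`` per event: (a) an unordered
    pair of side chains pointing at the same lattice site, and (b) a side
    chain pointing at the site of its own backbone neighbour (so a residue
    cannot bury its side chain "for free" along the chain axis)."""
    occ = system.occupancy()
    n = system.n_res
    targets = {}
    clashes = 0
    g = 0
    for chain in system.chains:
        for t in map(tuple, chain.positions + DIRECTIONS[chain.side_dirs]):
            targets[t] = targets.get(t, 0) + 1
            h = occ.get(t)
            if h is not None and g // n == h // n and abs(g - h) == 1:
                clashes += 1
            g += 1
    clashes += sum(c * (c - 1) // 2 for c in targets.values())
    return tables.steric_penalty * clashes


def total_energy(
    system: LatticeSystem,
    tables: InteractionTables,
    hparams: HydrophobicParams,
    t: float,
) -> EnergyBreakdown:
    """Evaluate all five Hamiltonian terms at temperature ``t``."""
    if t <= 0:
        raise ValueError("temperature must be > 0")
    k_solv = _exposure(system)
    codes = np.tile(system.sequence.codes, len(system.chains))
    hyd = np.tile(system.sequence.hydrophobic_flags, len(system.chains))
    exposed_h = k_solv & hyd
    c_h = int(exposed_h.sum())
    e_solv_const = float(np.sum(k_solv * tables.solvent_energies[codes]))
    f_hydr_sum = -hparams.alpha * (t - hparams.t0) ** 2 * c_h
    e_hydr_sum = -hparams.alpha * (hparams.t0 ** 2 - t ** 2) * c_h
    return EnergyBreakdown(
        e_hb=hb_energy(system, tables),
        e_steric=steric_energy(system, tables),
        e_state=state_energy(system, tables),
        e_aa=pair_energy(system, tables),
        phi_solvent=e_solv_const + f_hydr_sum,
        e_solv_exposed=e_solv_const,
        e_hydr_exposed=e_hydr_sum,
        c_h_exposed=c_h,
    )
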