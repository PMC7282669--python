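"""Cubic-lattice geometry of peptides, the fibril seed, and order parameters.

Each residue occupies one integer lattice site; consecutive residues sit on
nearest-neighbour sites.  A residue additionally carries a side-chain
*orientation* (one of the six axis directions) and a boolean beta-strand
state.  Empty sites are solvent; a side chain "sees" solvent when the site it
points at is unoccupied (sites outside the hard-wall box count as solvent).

The fibril seed is a double beta-sheet: every layer consists of two
anti-facing, in-register strands whose hydrophobic side chains point at each
other's backbone across the inter-sheet core; successive layers stack along
the fibril axis (z).  For the default 7-mer TFTFTFT this geometry yields the
model's two pinned order-parameter constants from first principles:

* docking one layer (two chains) creates 7 intra-layer + 2*7 inter-layer
  backbone contacts, so the fully docked layer has ``C_ext = 21``;
* each chain buries its 3 phenylalanine side chains in the core, so the
  exposed-hydrophobic count drops by ``dC_h = 6`` between the monomeric and
  fibrillar references.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence as TypingSequence

import numpy as np

__all__ = [
    "HYDROPHOBIC_RESIDUES",
    "AA_ALPHABET",
    "DIRECTIONS",
    "Sequence",
    "Conformation",
    "LatticeSystem",
    "OrderParams",
    "build_seed",
    "reference_fibrillar_state",
    "reference_monomeric_state",
    "count_external_contacts",
    "count_exposed_hydrophobic",
    "native_contact_sets",
    "native_fraction",
    "order_params",
    "validate_system",
    "system_to_text",
    "system_from_text",
]

#: Hydrophobic one-letter codes (residues with a positive solvent energy).
HYDROPHOBIC_RESIDUES = frozenset("CFLWVIMYA")

#: Canonical residue ordering used by all 20x20 / 20-entry parameter tables.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: The six axis unit vectors a side chain may point along.
DIRECTIONS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)
DIR_PLUS_Y, DIR_MINUS_Y, DIR_PLUS_Z = 2, 3, 4

#: Indices of the three positive axis directions (for unordered pair scans).
POSITIVE_DIRS = (0, 2, 4)


@dataclass(frozen=True)
class Sequence:
    """A peptide sequence with per-residue hydrophobicity flags."""

    residues: str

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        if len(seq) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = [c for c in seq if c not in AA_INDEX]
        if bad:
            raise ValueError(f"unknown residue code(s): {bad}")
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def hydrophobic_flags(self) -> np.ndarray:
        return np.array([r in HYDROPHOBIC_RESIDUES for r in self.residues])

    @property
    def codes(self) -> np.ndarray:
        """Residue indices into :data:`AA_ALPHABET` order."""
        return np.array([AA_INDEX[r] for r in self.residues], dtype=np.int64)


@dataclass
class Conformation:
    """Backbone positions, side-chain directions and beta states of one chain."""

    positions: np.ndarray  # (n, 3) int
    side_dirs: np.ndarray  # (n,) int in [0, 6)
    beta_flags: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.side_dirs = np.asarray(self.side_dirs, dtype=np.int64)
        self.beta_flags = np.asarray(self.beta_flags, dtype=bool)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n, 3)")
        if self.side_dirs.shape != (n,) or self.beta_flags.shape != (n,):
            raise ValueError("side_dirs/beta_flags must be (n,)")
        if np.any((self.side_dirs < 0) | (self.side_dirs >= 6)):
            raise ValueError("side_dirs must be in [0, 6)")

    def copy(self) -> "Conformation":
        return Conformation(
            self.positions.copy(), self.side_dirs.copy(), self.beta_flags.copy()
        )


@dataclass
class LatticeSystem:
    """Seed plus free chains in a hard-wall cubic box.

    ``chains[:n_seed]`` are the frozen seed strands (internally rigid during
    sampling); the remainder are the free chains.  All chains share one
    sequence.
    """

    sequence: Sequence
    chains: List[Conformation]
    n_seed: int
    box: int = 20
    # Seed placement bookkeeping so reference states can be constructed.
    seed_origin: tuple = field(default=(0, 0, 0))
    n_layers: int = 0

    @property
    def n_free(self) -> int:
        return len(self.chains) - self.n_seed

    @property
    def n_res(self) -> int:
        return len(self.sequence)

    def copy(self) -> "LatticeSystem":
        return LatticeSystem(
            sequence=self.sequence,
            chains=[c.copy() for c in self.chains],
            n_seed=self.n_seed,
            box=self.box,
            seed_origin=self.seed_origin,
            n_layers=self.n_layers,
        )

    def all_positions(self) -> np.ndarray:
        return np.concatenate([c.positions for c in self.chains])

    def occupancy(self) -> dict:
        """Map from occupied site (tuple) to global residue index."""
        occ = {}
        g = 0
        for chain in self.chains:
            for p in chain.positions:
                occ[tuple(p)] = g
                g += 1
        return occ


@dataclass(frozen=True)
class OrderParams:
    """The simulation order parameters of one configuration."""

    c_ext: int
    native_fraction: float
    c_h_exposed: int


def _strand_side_dirs(seq: Sequence, sheet: int) -> np.ndarray:
    """Side-chain directions for a strand in sheet 0 (+y core) or 1 (-y core).

    Hydrophobic side chains point across the inter-sheet gap at the partner
    strand's backbone (buried); polar side chains point away from the core
    (solvent-exposed), the natural alternation of a beta-strand.
    """
    into_core = DIR_PLUS_Y if sheet == 0 else DIR_MINUS_Y
    away = DIR_MINUS_Y if sheet == 0 else DIR_PLUS_Y
    return np.array(
        [into_core if h else away for h in seq.hydrophobic_flags], dtype=np.int64
    )


def _strand(seq: Sequence, x0: int, y: int, z: int, sheet: int) -> Conformation:
    n = len(seq)
    pos = np.stack(
        [np.arange(x0, x0 + n), np.full(n, y), np.full(n, z)], axis=1
    ).astype(np.int64)
    return Conformation(pos, _strand_side_dirs(seq, sheet), np.ones(n, dtype=bool))


def _free_chain_slots(box: int, n: int):
    """Two extended, mutually distant placements for the free chains."""
    x0 = (box - n) // 2
    return [(x0, 2, 3), (x0, box - 3, box - 4)]


def build_seed(
    sequence: Sequence | str = "TFTFTFT", n_layers: int = 4, box: int = 20
) -> LatticeSystem:
    """Construct the frozen double-sheet seed plus two dissociated free chains.

    The seed holds ``2 * n_layers`` strands (8 by default).  The two free
    chains start extended and far from the seed (the monomeric reference
    placement).
    """
    seq = Sequence(sequence) if isinstance(sequence, str) else sequence
    n = len(seq)
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    x0 = (box - n) // 2
    y0 = box // 2 - 1
    z0 = (box - n_layers) // 2
    if x0 < 1 or z0 < 1 or y0 < 5 or box - (y0 + 2) < 5 or z0 + n_layers + 2 > box:
        raise ValueError(
            f"box edge {box} too small for a {n}-mer seed with {n_layers} layers "
            "plus separated free chains"
        )
    chains = [
        _strand(seq, x0, y0 + sheet, z0 + layer, sheet)
        for layer in range(n_layers)
        for sheet in (0, 1)
    ]
    for (fx, fy, fz) in _free_chain_slots(box, n):
        pos = np.stack(
            [np.arange(fx, fx + n), np.full(n, fy), np.full(n, fz)], axis=1
        ).astype(np.int64)
        chains.append(
            Conformation(
                pos,
                np.full(n, DIR_PLUS_Z, dtype=np.int64),
                np.zeros(n, dtype=bool),
            )
        )
    system = LatticeSystem(
        sequence=seq,
        chains=chains,
        n_seed=2 * n_layers,
        box=box,
        seed_origin=(x0, y0, z0),
        n_layers=n_layers,
    )
    validate_system(system)
    return system


def reference_fibrillar_state(system: LatticeSystem) -> LatticeSystem:
    """Both free chains docked as the next in-register layer on the seed top."""
    out = system.copy()
    x0, y0, z0 = out.seed_origin
    z_new = z0 + out.n_layers
    seq = out.sequence
    for sheet, chain_idx in ((0, out.n_seed), (1, out.n_seed + 1)):
        out.chains[chain_idx] = _strand(seq, x0, y0 + sheet, z_new, sheet)
    validate_system(out)
    return out


def reference_monomeric_state(system: LatticeSystem) -> LatticeSystem:
    """Both free chains extended, separated from each other and from the seed."""
    out = system.copy()
    n = out.n_res
    for chain_idx, (fx, fy, fz) in zip(
        range(out.n_seed, len(out.chains)), _free_chain_slots(out.box, n)
    ):
        pos = np.stack(
            [np.arange(fx, fx + n), np.full(n, fy), np.full(n, fz)], axis=1
        ).astype(np.int64)
        out.chains[chain_idx] = Conformation(
            pos, np.full(n, DIR_PLUS_Z, dtype=np.int64), np.zeros(n, dtype=bool)
        )
    validate_system(out)
    return out


def _global_chain_ids(system: LatticeSystem) -> np.ndarray:
    n = system.n_res
    return np.repeat(np.arange(len(system.chains)), n)


def count_external_contacts(system: LatticeSystem) -> int:
    """Unordered nearest-neighbour residue pairs across molecules, with at
    least one residue in a free chain."""
    occ = system.occupancy()
    chain_of = _global_chain_ids(system)
    n = system.n_res
    count = 0
    for g, p in enumerate(system.all_positions()):
        for step in DIRECTIONS[list(POSITIVE_DIRS)]:  # unordered: +x, +y, +z only
            q = tuple(p + step)
            if q in occ:
                h = occ[q]
                if chain_of[g] != chain_of[h] and (
                    chain_of[g] >= system.n_seed or chain_of[h] >= system.n_seed
                ):
                    count += 1
    return count


def count_exposed_hydrophobic(system: LatticeSystem) -> int:
    """Number of free-chain hydrophobic side chains pointing at solvent.

    A side chain is solvent-exposed when the site it points at is unoccupied;
    sites beyond the hard wall also count as solvent.
    """
    occ = system.occupancy()
    hyd = system.sequence.hydrophobic_flags
    count = 0
    for chain in system.chains[system.n_seed :]:
        targets = chain.positions + DIRECTIONS[chain.side_dirs]
        for i, tgt in enumerate(targets):
            if hyd[i] and tuple(tgt) not in occ:
                count += 1
    return count


def native_contact_sets(system: LatticeSystem) -> List[np.ndarray]:
    """Reference fibril contacts as global residue-index pairs.

    Symmetry-equivalent docking variants are enumerated: the two free chains
    may dock with either sheet assignment, onto either fibril end (top or
    bottom layer), and either chain may dock with reversed backbone direction
    (for the palindromic default sequence a reversed strand forms the
    identical structure).  Each variant is a (3n, 2) array of pairs: n
    lateral pairs between the two free chains plus 2n in-register pairs to
    the adjacent seed layer; 16 variants in total.
    """
    n = system.n_res
    n_seed = system.n_seed
    free_a, free_b = n_seed, n_seed + 1
    top_a, top_b = n_seed - 2, n_seed - 1  # last layer, sheets 0 and 1
    bot_a, bot_b = 0, 1  # first layer
    variants = []
    for ca, cb in ((free_a, free_b), (free_b, free_a)):
        for sa, sb in ((top_a, top_b), (bot_a, bot_b)):
            for rev_a in (False, True):
                for rev_b in (False, True):
                    ra = (lambda i: n - 1 - i) if rev_a else (lambda i: i)
                    rb = (lambda i: n - 1 - i) if rev_b else (lambda i: i)
                    pairs = []
                    for i in range(n):
                        pairs.append((ca * n + ra(i), cb * n + rb(i)))  # lateral
                        pairs.append((ca * n + ra(i), sa * n + i))
                        pairs.append((cb * n + rb(i), sb * n + i))
                    variants.append(np.array(pairs, dtype=np.int64))
    return variants


def native_fraction(system: LatticeSystem) -> float:
    """Fraction of reference fibril contacts present (best docking variant)."""
    pos = system.all_positions()
    best = 0
    for pairs in native_contact_sets(system):
        d = np.abs(pos[pairs[:, 0]] - pos[pairs[:, 1]]).sum(axis=1)
        best = max(best, int(np.sum(d == 1)))
    return best / (3 * system.n_res)


def order_params(system: LatticeSystem) -> OrderParams:
    return OrderParams(
        c_ext=count_external_contacts(system),
        native_fraction=native_fraction(system),
        c_h_exposed=count_exposed_hydrophobic(system),
    )


def validate_system(system: LatticeSystem) -> None:
    """Full-system validation: bounds, connectivity, global self-avoidance."""
    seen = set()
    for ci, chain in enumerate(system.chains):
        pos = chain.positions
        if len(pos) != system.n_res:
            raise ValueError(f"chain {ci} length mismatch")
        if np.any(pos < 0) or np.any(pos >= system.box):
            raise ValueError(f"chain {ci} leaves the box")
        steps = np.abs(np.diff(pos, axis=0)).sum(axis=1)
        if np.any(steps != 1):
            raise ValueError(f"chain {ci} breaks backbone connectivity")
        for p in map(tuple, pos):
            if p in seen:
                raise ValueError(f"steric overlap at site {p}")
            seen.add(p)


def system_to_text(system: LatticeSystem) -> str:
    """Serialise to the documented plain-text format (one residue per line:
    chain id, residue index, x, y, z, side-dir, beta-flag)."""
    lines = [
        f"# amylattice system box={system.box} n_seed={system.n_seed} "
        f"sequence={system.sequence.residues} "
        f"seed_origin={','.join(map(str, system.seed_origin))} "
        f"n_layers={system.n_layers}"
    ]
    for ci, chain in enumerate(system.chains):
        for i in range(len(chain.positions)):
            x, y, z = chain.positions[i]
            lines.append(
                f"{ci}\t{i}\t{x}\t{y}\t{z}\t{chain.side_dirs[i]}\t"
                f"{int(chain.beta_flags[i])}"
            )
    return "\n".join(lines) + "\n"


def system_from_text(text: str) -> LatticeSystem:
    """Parse the plain-text system format written by :func:`system_to_text`."""
    header = None
    rows = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if header is None:
                header = dict(
                    kv.split("=", 1) for kv in line.lstrip("# ").split()[2:]
                )
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError(f"line {ln}: expected 7 tab-separated fields")
        rows.append([int(v) for v in parts])
    if header is None:
        raise ValueError("missing header line")
    seq = Sequence(header["sequence"])
    n = len(seq)
    rows.sort(key=lambda r: (r[0], r[1]))
    n_chains = rows[-1][0] + 1
    chains = []
    for ci in range(n_chains):
        cr = [r for r in rows if r[0] == ci]
        if [r[1] for r in cr] != list(range(n)):
            raise ValueError(f"chain {ci}: residue indices not 0..{n - 1}")
        chains.append(
            Conformation(
                np.array([r[2:5] for r in cr]),
                np.array([r[5] for r in cr]),
                np.array([bool(r[6]) for r in cr]),
            )
        )
    system = LatticeSystem(
        sequence=seq,
        chains=chains,
        n_seed=int(header["n_seed"]),
        box=int(header["box"]),
        seed_origin=tuple(int(v) for v in header["seed_origin"].split(",")),
        n_layers=int(header["n_layers"]),
    )
    validate_system(system)
    return system
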