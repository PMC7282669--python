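"""Metropolis Monte Carlo sampling of fibril elongation.

Two free chains move against a frozen seed (only rigid-body moves are
allowed for the seed) over a temperature grid, optionally coupled by replica
exchange.  Acceptance uses the full Hamiltonian ``H(T)`` directly -- the
solvation term is a potential of mean force -- while physical enthalpies are
measured with the Gibbs-Helmholtz estimator (``F_hydr`` replaced by
``E_hydr`` per exposed hydrophobic contact), which reduces to ``H`` when
``alpha = 0``.

The move set mixes local chain moves (end rotation, corner flip,
crankshaft), rigid free-chain translations/rotations/teleports, side-chain
re-orientations, beta-state flips and rigid seed translations/rotations.
Every proposal distribution is symmetric; invalid proposals (wall or
excluded-volume violations) are rejected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from . import _kernels as K
from .hamiltonian import EnergyBreakdown, InteractionTables
from .lattice import LatticeSystem, native_contact_sets
from .thermo import HydrophobicParams

__all__ = [
    "MOVE_NAMES",
    "DEFAULT_MOVE_WEIGHTS",
    "MCConfig",
    "PackedState",
    "ElongationRun",
    "pack_system",
    "unpack_system",
    "metropolis_step",
    "run_elongation",
    "enthalpy_estimator",
    "sweep_parameters",
]

MOVE_NAMES = (
    "end_rotation",
    "corner_flip",
    "crankshaft",
    "chain_translation",
    "chain_rotation",
    "side_flip",
    "beta_flip",
    "seed_translation",
    "seed_rotation",
    "chain_teleport",
)

DEFAULT_MOVE_WEIGHTS: Dict[str, float] = {
    "end_rotation": 0.15,
    "corner_flip": 0.20,
    "crankshaft": 0.15,
    "chain_translation": 0.15,
    "chain_rotation": 0.10,
    "side_flip": 0.15,
    "beta_flip": 0.10,
    "seed_translation": 0.02,
    "seed_rotation": 0.01,
    "chain_teleport": 0.03,
}


@dataclass(frozen=True)
class MCConfig:
    """Sampling protocol.

    ``sweeps`` counts Monte Carlo sweeps (one sweep = ``moves_per_sweep``
    elementary move attempts, by default the number of free residues plus
    two rigid-body attempts).  Samples are recorded every
    ``sample_interval`` sweeps after ``equilibration_sweeps``; replica
    exchange between adjacent temperatures is attempted at the same cadence.
    """

    temperatures: tuple = tuple(np.round(np.arange(0.15, 0.4501, 0.025), 4))
    sweeps: int = 100_000
    equilibration_sweeps: int = 25_000
    rng_seed: int = 0
    replica_exchange: bool = True
    sample_interval: int = 5
    moves_per_sweep: int = 0  # 0 -> n_free_residues + 2
    move_weights: tuple = tuple(sorted(DEFAULT_MOVE_WEIGHTS.items()))
    #: replica start states: "as_given", "monomeric", "fibrillar" or
    #: "alternating" (replicas alternate monomeric/fibrillar so equilibrium
    #: is approached from both sides of the docking transition).
    start: str = "alternating"

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.temperatures)
        if any(t <= 0 for t in ts):
            raise ValueError("temperatures must be positive")
        if list(ts) != sorted(ts):
            raise ValueError("temperatures must be sorted ascending")
        if not (self.sweeps > self.equilibration_sweeps >= 0):
            raise ValueError("need sweeps > equilibration_sweeps >= 0")
        object.__setattr__(self, "temperatures", ts)

    def cumulative_move_weights(self) -> np.ndarray:
        w = dict(self.move_weights)
        weights = np.array([w.get(name, 0.0) for name in MOVE_NAMES], dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("move weights must be non-negative and not all zero")
        return np.cumsum(weights / weights.sum())


class PackedState:
    """Flat-array representation of a :class:`LatticeSystem` for the kernels."""

    def __init__(
        self,
        system: LatticeSystem,
        tables: InteractionTables,
        hparams: HydrophobicParams,
        t: float,
    ):
        self.template = system.copy()
        self.n = system.n_res
        self.n_chains = len(system.chains)
        self.n_seed_chains = system.n_seed
        self.L = system.box
        self.pos = system.all_positions().copy()
        self.sdir = np.concatenate([c.side_dirs for c in system.chains]).astype(
            np.int64
        )
        self.beta = np.concatenate([c.beta_flags for c in system.chains]).astype(
            np.int64
        )
        self.codes = np.tile(system.sequence.codes, self.n_chains)
        self.hyd = np.tile(
            system.sequence.hydrophobic_flags, self.n_chains
        ).astype(np.int64)
        self.occ = np.zeros((self.L, self.L, self.L), dtype=np.int64)
        for g, p in enumerate(self.pos):
            if self.occ[p[0], p[1], p[2]] != 0:
                raise ValueError("system has overlapping residues")
            self.occ[p[0], p[1], p[2]] = g + 1
        self.scratch = np.zeros_like(self.occ)
        self.tables = tables
        self.hparams = hparams
        self.t = float(t)
        self.comp = np.zeros(K.N_COMPONENTS, dtype=np.float64)
        if system.n_seed >= 2 and system.n_layers >= 1:
            self.native_variants = np.stack(native_contact_sets(system))
        else:
            self.native_variants = np.zeros((1, 1, 2), dtype=np.int64)
        self.refresh_energy()

    def refresh_energy(self) -> None:
        K.energy_components(
            self.pos,
            self.sdir,
            self.beta,
            self.occ,
            self.codes,
            self.hyd,
            self.n,
            self.n_seed_chains,
            self.tables.pair_energies,
            self.tables.solvent_energies,
            self.tables.hb_strength,
            math.log(self.tables.beta_propensity),
            self.tables.steric_penalty,
            self.hparams.alpha,
            self.hparams.t0,
            self.t,
            self.scratch,
            self.comp,
        )

    def run(
        self,
        n_steps: int,
        rng_state: np.ndarray,
        move_cum: np.ndarray,
        move_attempts: np.ndarray,
        move_accepts: np.ndarray,
    ) -> int:
        return K.run_block(
            self.pos,
            self.sdir,
            self.beta,
            self.occ,
            self.codes,
            self.hyd,
            self.n,
            self.n_seed_chains,
            self.n_chains,
            self.tables.pair_energies,
            self.tables.solvent_energies,
            self.tables.hb_strength,
            math.log(self.tables.beta_propensity),
            self.tables.steric_penalty,
            self.hparams.alpha,
            self.hparams.t0,
            self.t,
            n_steps,
            rng_state,
            move_cum,
            self.scratch,
            self.comp,
            move_attempts,
            move_accepts,
        )

    # -- derived quantities from the cached component vector ----------------

    def total_at(self, t: float) -> float:
        """Hamiltonian of the current configuration at another temperature."""
        c_h = self.comp[K.C_H]
        f_new = -self.hparams.alpha * (t - self.hparams.t0) ** 2 * c_h
        return float(self.comp[K.TOTAL] - self.comp[K.F_HYDR] + f_new)

    def set_temperature(self, t: float) -> None:
        c_h = self.comp[K.C_H]
        self.comp[K.TOTAL] -= self.comp[K.F_HYDR]
        self.comp[K.F_HYDR] = -self.hparams.alpha * (t - self.hparams.t0) ** 2 * c_h
        self.comp[K.E_HYDR] = (
            -self.hparams.alpha * (self.hparams.t0 ** 2 - t ** 2) * c_h
        )
        self.comp[K.TOTAL] += self.comp[K.F_HYDR]
        self.t = float(t)

    @property
    def enthalpy_estimate(self) -> float:
        return float(self.comp[K.TOTAL] - self.comp[K.F_HYDR] + self.comp[K.E_HYDR])

    def native_count(self) -> int:
        if self.native_variants.shape[1] <= 1:
            return 0
        return int(K.native_contact_count(self.pos, self.native_variants))

    def breakdown(self) -> EnergyBreakdown:
        c = self.comp
        return EnergyBreakdown(
            e_hb=float(c[K.E_HB]),
            e_steric=float(c[K.E_STERIC]),
            e_state=float(c[K.E_STATE]),
            e_aa=float(c[K.E_AA]),
            phi_solvent=float(c[K.E_SOLV] + c[K.F_HYDR]),
            e_solv_exposed=float(c[K.E_SOLV]),
            e_hydr_exposed=float(c[K.E_HYDR]),
            c_h_exposed=int(c[K.C_H]),
        )


def pack_system(
    system: LatticeSystem,
    tables: InteractionTables,
    hparams: HydrophobicParams,
    t: float,
) -> PackedState:
    return PackedState(system, tables, hparams, t)


def unpack_system(state: PackedState) -> LatticeSystem:
    out = state.template.copy()
    n = state.n
    for ci, chain in enumerate(out.chains):
        sl = slice(ci * n, (ci + 1) * n)
        chain.positions = state.pos[sl].copy()
        chain.side_dirs = state.sdir[sl].copy()
        chain.beta_flags = state.beta[sl].astype(bool)
    return out


def _rng_state_from(seed_seq: np.random.SeedSequence) -> np.ndarray:
    words = seed_seq.generate_state(2, dtype=np.uint64)
    words[words == 0] = 0x9E3779B97F4A7C15
    return words.copy()


def metropolis_step(
    system: LatticeSystem,
    tables: InteractionTables,
    hparams: HydrophobicParams,
    t: float,
    rng_state: np.ndarray,
    move_weights: Optional[Dict[str, float]] = None,
) -> tuple:
    """One Metropolis step on a :class:`LatticeSystem`; returns
    ``(accepted, new_system)``.

    Convenience wrapper around the compiled kernel (re-packs the system each
    call; use :func:`run_elongation` for production sampling).
    """
    state = pack_system(system, tables, hparams, t)
    weights = dict(DEFAULT_MOVE_WEIGHTS if move_weights is None else move_weights)
    cfg = MCConfig(
        temperatures=(t,), sweeps=1, equilibration_sweeps=0,
        move_weights=tuple(sorted(weights.items())),
    )
    attempts = np.zeros(K.N_MOVE_TYPES, dtype=np.int64)
    accepts = np.zeros(K.N_MOVE_TYPES, dtype=np.int64)
    n_acc = state.run(1, rng_state, cfg.cumulative_move_weights(), attempts, accepts)
    return bool(n_acc), unpack_system(state)


def enthalpy_estimator(breakdown: EnergyBreakdown) -> float:
    """Physical enthalpy of a configuration under the temperature-dependent
    Hamiltonian: every temperature-independent term plus the Gibbs-Helmholtz
    ``E_hydr`` of each exposed hydrophobic contact.  Not equal to ``H`` when
    ``alpha != 0``."""
    return breakdown.enthalpy_estimate


@dataclass
class ElongationRun:
    """Result of one elongation sampling run.

    ``samples`` is a long-format DataFrame with one row per retained sample:
    temperature, sweep, order parameters, the five Hamiltonian terms, the
    total, ``e_int`` and the enthalpy estimate.  ``move_stats`` holds
    per-move attempt/accept counts summed over replicas; ``swap_rate`` the
    replica-exchange acceptance fraction.
    """

    config: MCConfig
    samples: pd.DataFrame
    move_stats: pd.DataFrame
    swap_rate: float
    final_systems: dict = field(default_factory=dict)

    def at_temperature(self, t: float) -> pd.DataFrame:
        return self.samples[np.isclose(self.samples["temperature"], t)]


def _start_systems(start: str, system: LatticeSystem, n_t: int) -> list:
    """Initial configurations per replica (see :class:`MCConfig.start`)."""
    from .lattice import reference_fibrillar_state, reference_monomeric_state

    has_seed = system.n_seed >= 2 and system.n_layers >= 1
    if start == "as_given" or not has_seed:
        return [system] * n_t
    if start == "monomeric":
        return [reference_monomeric_state(system)] * n_t
    if start == "fibrillar":
        return [reference_fibrillar_state(system)] * n_t
    if start == "alternating":
        mono = reference_monomeric_state(system)
        fib = reference_fibrillar_state(system)
        return [mono if i % 2 == 0 else fib for i in range(n_t)]
    raise ValueError(f"unknown start mode: {start!r}")


def run_elongation(
    config: MCConfig,
    system: LatticeSystem,
    tables: InteractionTables,
    hparams: HydrophobicParams,
    keep_final_systems: bool = False,
) -> ElongationRun:
    """Sample the elongation equilibrium over the configured temperature grid.

    Deterministic for a fixed ``config.rng_seed``.  With
    ``config.replica_exchange`` the replicas attempt nearest-neighbour
    temperature swaps (alternating parity) every ``sample_interval`` sweeps,
    using the exchange criterion appropriate for a temperature-dependent
    Hamiltonian (both configurations re-evaluated at both temperatures).
    """
    temps = list(config.temperatures)
    n_t = len(temps)
    move_cum = config.cumulative_move_weights()
    root = np.random.SeedSequence(config.rng_seed)
    replica_seeds = root.spawn(n_t + 1)
    swap_rng = np.random.default_rng(replica_seeds[-1])
    start_systems = _start_systems(config.start, system, n_t)
    states = [pack_system(start_systems[i], tables, hparams, t) for i, t in enumerate(temps)]
    rngs = [_rng_state_from(s) for s in replica_seeds[:n_t]]
    attempts = np.zeros(K.N_MOVE_TYPES, dtype=np.int64)
    accepts = np.zeros(K.N_MOVE_TYPES, dtype=np.int64)

    moves_per_sweep = config.moves_per_sweep
    if moves_per_sweep <= 0:
        moves_per_sweep = system.n_free * system.n_res + 2

    block = config.sample_interval
    n_blocks = config.sweeps // block
    swap_attempts = 0
    swap_accepts = 0
    records = []

    for ib in range(n_blocks):
        sweep = (ib + 1) * block
        for i in range(n_t):
            states[i].run(block * moves_per_sweep, rngs[i], move_cum, attempts, accepts)
        if config.replica_exchange and n_t > 1:
            for i in range(ib % 2, n_t - 1, 2):
                ti, tj = temps[i], temps[i + 1]
                si, sj = states[i], states[i + 1]
                delta = (si.total_at(ti) - sj.total_at(ti)) / ti + (
                    sj.total_at(tj) - si.total_at(tj)
                ) / tj
                swap_attempts += 1
                # delta as defined: accept swap with min(1, exp(+delta))
                if delta >= 0 or swap_rng.random() < math.exp(delta):
                    swap_accepts += 1
                    states[i], states[i + 1] = states[i + 1], states[i]
                    states[i].set_temperature(ti)
                    states[i + 1].set_temperature(tj)
        if sweep > config.equilibration_sweeps:
            for i in range(n_t):
                st = states[i]
                c = st.comp
                records.append(
                    (
                        temps[i],
                        sweep,
                        int(c[K.C_EXT]),
                        st.native_count() / max(1, st.native_variants.shape[1]),
                        int(c[K.C_H_FREE]),
                        c[K.E_HB],
                        c[K.E_STERIC],
                        c[K.E_STATE],
                        c[K.E_AA],
                        c[K.E_SOLV] + c[K.F_HYDR],
                        c[K.TOTAL],
                        c[K.TOTAL] - c[K.E_SOLV] - c[K.F_HYDR],
                        st.enthalpy_estimate,
                    )
                )

    samples = pd.DataFrame(
        records,
        columns=[
            "temperature",
            "sweep",
            "c_ext",
            "native_fraction",
            "c_h_exposed",
            "e_hb",
            "e_steric",
            "e_state",
            "e_aa",
            "phi_solvent",
            "total",
            "e_int",
            "enthalpy_est",
        ],
    )
    move_stats = pd.DataFrame(
        {"move": MOVE_NAMES, "attempts": attempts, "accepts": accepts}
    )
    run = ElongationRun(
        config=config,
        samples=samples,
        move_stats=move_stats,
        swap_rate=swap_accepts / swap_attempts if swap_attempts else float("nan"),
    )
    if keep_final_systems:
        run.final_systems = {temps[i]: unpack_system(states[i]) for i in range(n_t)}
    return run


def sweep_parameters(
    config: MCConfig,
    system: LatticeSystem,
    tables: InteractionTables,
    hparams: HydrophobicParams,
    grid: Dict[str, Iterable[float]],
) -> Dict[tuple, object]:
    """Run :func:`run_elongation` over a parameter grid.

    ``grid`` maps parameter names (``alpha``, ``eps_hb``, ``n_beta``) to the
    values to sweep.  Each cell gets a reproducible sub-seed derived from the
    base seed.  Per-cell failures are isolated: the cell's value is then the
    raised exception rather than a run.
    """
    allowed = {"alpha", "eps_hb", "n_beta"}
    bad = set(grid) - allowed
    if bad:
        raise ValueError(f"unknown sweep parameter(s): {sorted(bad)}")
    names = sorted(grid)
    cells = list(itertools.product(*(list(grid[name]) for name in names)))
    root = np.random.SeedSequence(config.rng_seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(len(cells))]
    results: Dict[tuple, object] = {}
    for cell, sub_seed in zip(cells, sub_seeds):
        params = dict(zip(names, cell))
        cell_tables = tables
        overrides = {}
        if "eps_hb" in params:
            overrides["hb_strength"] = params["eps_hb"]
        if "n_beta" in params:
            overrides["beta_propensity"] = params["n_beta"]
        if overrides:
            cell_tables = replace(tables, **overrides)
        cell_hparams = (
            HydrophobicParams(alpha=params["alpha"], t0=hparams.t0)
            if "alpha" in params
            else hparams
        )
        cell_config = replace(config, rng_seed=sub_seed)
        key = tuple(sorted(params.items()))
        try:
            results[key] = run_elongation(cell_config, system, cell_tables, cell_hparams)
        except Exception as exc:  # pragma: no cover - defensive isolation
            results[key] = exc
    return results
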