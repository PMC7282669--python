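"""Monte Carlo engine: determinism, constraints, and enumeration oracles.

The key correctness checks compare sampled distributions of small, fully
enumerable systems against exact Boltzmann sums computed by an independent
brute-force oracle in this file.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from amylattice import mc
from amylattice import _kernels as K
from amylattice.hamiltonian import total_energy
from amylattice.lattice import (
    Conformation,
    DIRECTIONS,
    LatticeSystem,
    Sequence,
    build_seed,
    reference_fibrillar_state,
)
from amylattice.landscape import elongation_curves
from amylattice.thermo import HydrophobicParams

from conftest import toy_tables

NO_SEED_WEIGHTS = tuple(
    sorted(
        {
            **mc.DEFAULT_MOVE_WEIGHTS,
            "seed_translation": 0.0,
            "seed_rotation": 0.0,
            "beta_flip": 0.05,
        }.items()
    )
)


def toy_monomer_system(box=3):
    """One free FFF 3-mer in a tiny box: a fully enumerable system."""
    seq = Sequence("FFF")
    pos = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
    chain = Conformation(pos, np.array([4, 4, 4]), np.zeros(3, dtype=bool))
    return LatticeSystem(sequence=seq, chains=[chain], n_seed=0, box=box)


def toy_seeded_system(box=4):
    """A frozen FFF strand plus one free FFF 3-mer (enumerable docking toy).

    The seed is non-beta so hydrogen bonds never form and the beta flags of
    the free chain decouple exactly from its conformation.
    """
    seq = Sequence("FFF")
    seed = Conformation(
        np.array([[0, 1, 1], [1, 1, 1], [2, 1, 1]]),
        np.array([2, 2, 2]),  # +y
        np.zeros(3, dtype=bool),
    )
    free = Conformation(
        np.array([[0, 3, 3], [1, 3, 3], [2, 3, 3]]),
        np.array([4, 4, 4]),
        np.zeros(3, dtype=bool),
    )
    return LatticeSystem(sequence=seq, chains=[seed, free], n_seed=1, box=box)


def _saw_backbones(box, n, occupied=()):
    """All self-avoiding n-mers inside the box avoiding ``occupied`` sites."""
    occ = set(map(tuple, occupied))
    sites = [
        (x, y, z)
        for x in range(box)
        for y in range(box)
        for z in range(box)
        if (x, y, z) not in occ
    ]
    out = []

    def extend(path):
        if len(path) == n:
            out.append(list(path))
            return
        x, y, z = path[-1]
        for dx, dy, dz in DIRECTIONS:
            q = (x + dx, y + dy, z + dz)
            if (
                0 <= q[0] < box
                and 0 <= q[1] < box
                and 0 <= q[2] < box
                and q not in occ
                and q not in path
            ):
                extend(path + [q])

    for s in sites:
        extend([s])
    return out


def _enumerate_toy(system, tables, hparams, t):
    """Exact Boltzmann distribution of the free chain's (backbone, side-dir)
    microstates, via brute force over all configurations.

    Returns a dict mapping an observable key
    (c_ext, c_h_exposed, e_aa, e_steric) -> probability.  Beta flags decouple
    (no hydrogen-bond partners are possible) and are marginalised out.
    """
    box = system.box
    n = system.n_res
    eps_pair = tables.pair_energies
    eps_solv = tables.solvent_energies
    codes = system.sequence.codes
    hyd = system.sequence.hydrophobic_flags
    f_contact = -hparams.alpha * (t - hparams.t0) ** 2
    seed_sites = {}
    seed_targets = []
    if system.n_seed:
        seed = system.chains[0]
        for i, p in enumerate(seed.positions):
            seed_sites[tuple(p)] = i
        seed_targets = [tuple(p + DIRECTIONS[d]) for p, d in zip(seed.positions, seed.side_dirs)]

    weights = {}
    z_total = 0.0
    for backbone in _saw_backbones(box, n, occupied=list(seed_sites)):
        own = {tuple(p): i for i, p in enumerate(backbone)}
        # seed side chains: directed pair energy when pointing at the free
        # chain, solvation (plus hydrophobic term) when pointing at solvent
        e_seed_point = 0.0
        for i, tgt in enumerate(seed_targets):
            if tgt in own:
                e_seed_point += eps_pair[codes[i], codes[own[tgt]]]
            else:
                inside = all(0 <= c < box for c in tgt)
                if not inside or tgt not in seed_sites:
                    e_seed_point += eps_solv[codes[i]]
                    if hyd[i]:
                        e_seed_point += f_contact
        # external contacts (backbone adjacency, free-seed)
        c_ext = 0
        for p in backbone:
            for d in DIRECTIONS:
                if (p[0] + d[0], p[1] + d[1], p[2] + d[2]) in seed_sites:
                    c_ext += 1
        for sdirs in itertools.product(range(6), repeat=n):
            e = e_seed_point
            c_h = 0
            steric = 0
            targets = []
            for i, (p, sd) in enumerate(zip(backbone, sdirs)):
                tgt = (
                    p[0] + DIRECTIONS[sd][0],
                    p[1] + DIRECTIONS[sd][1],
                    p[2] + DIRECTIONS[sd][2],
                )
                targets.append(tgt)
                inside = all(0 <= c < box for c in tgt)
                if not inside or (tgt not in own and tgt not in seed_sites):
                    e += eps_solv[codes[i]]
                    if hyd[i]:
                        e += f_contact
                        c_h += 1
                elif tgt in seed_sites:
                    e += eps_pair[codes[i], codes[seed_sites[tgt]]]
                else:  # own chain
                    j = own[tgt]
                    if abs(i - j) == 1:
                        steric += 1
                    else:
                        e += eps_pair[codes[i], codes[j]]
            for a in range(n):
                for b in range(a + 1, n):
                    if targets[a] == targets[b] and all(
                        0 <= c < box for c in targets[a]
                    ):
                        steric += 1
                # free and seed side chains pointing at the same site
            for tgt in targets:
                if all(0 <= c < box for c in tgt):
                    steric += seed_targets.count(tgt)
            e += tables.steric_penalty * steric
            w = np.exp(-e / t)
            obs = (c_ext, c_h)
            weights[obs] = weights.get(obs, 0.0) + w
            z_total += w
    return {k: v / z_total for k, v in weights.items()}


def _run_toy(system, tables, hparams, t, sweeps, seed):
    cfg = mc.MCConfig(
        temperatures=(t,),
        sweeps=sweeps,
        equilibration_sweeps=sweeps // 5,
        rng_seed=seed,
        sample_interval=10,
        replica_exchange=False,
        move_weights=NO_SEED_WEIGHTS,
        start="as_given",
    )
    return mc.run_elongation(cfg, system, tables, hparams, keep_final_systems=True)


@pytest.mark.parametrize("t", [0.3, 0.5, 0.8])
def test_single_chain_sampling_matches_enumeration(t):
    """Long-run MC occupancies of a fully enumerable one-chain system match
    the exact Boltzmann distribution within conservative Monte Carlo error."""
    tables = toy_tables(eps_ff=-1.0, eps_f_solv=0.8, steric=2.0)
    hp = HydrophobicParams(alpha=10.0, t0=0.4)
    system = toy_monomer_system()
    exact = _enumerate_toy(system, tables, hp, t)
    run = _run_toy(system, tables, hp, t, sweeps=120_000, seed=11)
    samples = run.samples
    n = len(samples)
    n_eff = n / 10  # conservative correction for autocorrelation
    counts = samples.groupby(["c_ext", "c_h_exposed"]).size()
    for key, p in exact.items():
        if p < 0.01:
            continue
        p_mc = counts.get(key, 0) / n
        sigma = np.sqrt(p * (1 - p) / n_eff)
        assert abs(p_mc - p) < 3 * sigma + 0.005, (t, key, p, p_mc)


def test_seeded_toy_binding_free_energy_matches_partition_ratio():
    """dG between bound (c_ext > 0) and free states of the docking toy equals
    the exact partition-function ratio within the block-averaged error."""
    tables = toy_tables(eps_ff=-1.0, eps_f_solv=0.8, steric=2.0)
    hp = HydrophobicParams(alpha=10.0, t0=0.4)
    system = toy_seeded_system()
    for t in (0.7, 0.9):  # both states well populated (exact p_bound 0.84/0.39)
        exact = _enumerate_toy(system, tables, hp, t)
        p_bound = sum(p for (c_ext, _), p in exact.items() if c_ext > 0)
        dg_exact = -t * np.log(p_bound / (1 - p_bound))
        run = _run_toy(system, tables, hp, t, sweeps=150_000, seed=3)
        samples = run.samples
        labels = pd.Series(
            np.where(samples["c_ext"] > 0, "fibrillar", "monomeric"),
            index=samples.index,
        )
        curve = elongation_curves(samples, labels=labels, min_visits=50)
        assert curve.sampled[0]
        err = max(curve.delta_g_err[0], 0.02)
        assert curve.delta_g[0] == pytest.approx(dg_exact, abs=3 * err + 0.05)


def test_run_is_deterministic_for_fixed_seed(tables):
    system = build_seed("TFTFTFT")
    hp = HydrophobicParams(40.0, 0.4)
    cfg = mc.MCConfig(
        temperatures=(0.25, 0.35),
        sweeps=2000,
        equilibration_sweeps=200,
        rng_seed=99,
        sample_interval=5,
    )
    a = mc.run_elongation(cfg, system, tables, hp)
    b = mc.run_elongation(cfg, system, tables, hp)
    pd.testing.assert_frame_equal(a.samples, b.samples)
    assert a.swap_rate == b.swap_rate


def test_seed_stays_internally_rigid(tables):
    """Only rigid-body moves may touch the seed: its internal coordinates
    (positions relative to the first seed residue, in the seed frame) are
    preserved over a long hot run."""
    system = build_seed("TFTFTFT")
    hp = HydrophobicParams(0.0, 0.4)
    cfg = mc.MCConfig(
        temperatures=(2.0,),  # hot: nearly every proposal accepted
        sweeps=5000,
        equilibration_sweeps=0,
        rng_seed=1,
        sample_interval=1000,
        replica_exchange=False,
        start="as_given",
    )
    run = mc.run_elongation(cfg, system, tables, hp, keep_final_systems=True)
    final = run.final_systems[2.0]
    ref = np.concatenate(
        [c.positions for c in system.chains[: system.n_seed]]
    )
    got = np.concatenate([c.positions for c in final.chains[: final.n_seed]])
    ref_rel = ref - ref[0]
    got_rel = got - got[0]
    # the seed may have been rigidly rotated: relative distances are invariant
    d_ref = np.linalg.norm(ref_rel[:, None] - ref_rel[None, :], axis=-1)
    d_got = np.linalg.norm(got_rel[:, None] - got_rel[None, :], axis=-1)
    assert np.allclose(d_ref, d_got)


def test_move_mix_matches_configured_weights(tables):
    """Empirical proposal frequencies agree with the configured mix within
    3-sigma multinomial bounds."""
    system = build_seed("TFTFTFT")
    hp = HydrophobicParams(0.0, 0.4)
    state = mc.pack_system(system, tables, hp, 0.5)
    cfg = mc.MCConfig(temperatures=(0.5,), sweeps=1, equilibration_sweeps=0)
    cum = cfg.cumulative_move_weights()
    probs = np.diff(np.concatenate([[0.0], cum]))
    att = np.zeros(10, dtype=np.int64)
    acc = np.zeros(10, dtype=np.int64)
    rng = np.array([7, 13], dtype=np.uint64)
    n_steps = 60_000
    state.run(n_steps, rng, cum, att, acc)
    assert att.sum() == n_steps
    for k in range(10):
        sigma = np.sqrt(n_steps * probs[k] * (1 - probs[k]))
        assert abs(att[k] - n_steps * probs[k]) < 3 * sigma + 1


def test_running_energy_matches_full_recomputation(tables):
    """The engine's cached energy components never drift from an independent
    full recomputation (accept/reject bookkeeping is exact)."""
    hp = HydrophobicParams(60.0, 0.4)
    system = reference_fibrillar_state(build_seed("TFTFTFT"))
    state = mc.pack_system(system, tables, hp, 0.25)
    cfg = mc.MCConfig(temperatures=(0.25,), sweeps=1, equilibration_sweeps=0)
    rng = np.array([42, 4242], dtype=np.uint64)
    att = np.zeros(10, dtype=np.int64)
    acc = np.zeros(10, dtype=np.int64)
    for _ in range(20):
        state.run(5000, rng, cfg.cumulative_move_weights(), att, acc)
        cached = state.comp.copy()
        state.refresh_energy()
        assert np.allclose(cached, state.comp, atol=1e-9)


def test_enthalpy_estimator_reference_values(tables, monomeric, fibrillar):
    hp = HydrophobicParams(60.0, 0.4)
    b_mono = total_energy(monomeric, tables, hp, 0.2)
    # 6 exposed hydrophobic contacts, each contributing E_hydr = -7.2 and the
    # temperature-independent solvent energy; no estimator correction for the
    # buried fibrillar reference
    assert mc.enthalpy_estimator(b_mono) == pytest.approx(
        b_mono.e_int + b_mono.e_solv_exposed + 6 * (-60.0) * (0.16 - 0.04)
    )
    b_fib = total_energy(fibrillar, tables, hp, 0.2)
    assert mc.enthalpy_estimator(b_fib) == pytest.approx(b_fib.e_int)
    b0 = total_energy(monomeric, tables, HydrophobicParams(0.0, 0.4), 0.2)
    assert mc.enthalpy_estimator(b0) == pytest.approx(b0.total)


def test_metropolis_step_wrapper_roundtrip(tables):
    system = build_seed("TFTFTFT")
    hp = HydrophobicParams(0.0, 0.4)
    rng = np.array([5, 6], dtype=np.uint64)
    accepted, out = mc.metropolis_step(system, tables, hp, 0.4, rng)
    from amylattice.lattice import validate_system

    validate_system(out)


def test_sweep_parameters_grid(tables):
    system = build_seed("TFTFTFT")
    hp = HydrophobicParams(0.0, 0.4)
    cfg = mc.MCConfig(
        temperatures=(0.25, 0.4),
        sweeps=500,
        equilibration_sweeps=100,
        rng_seed=12,
        sample_interval=10,
    )
    results = mc.sweep_parameters(
        cfg, system, tables, hp, {"alpha": [0.0, 40.0], "eps_hb": [-1.4]}
    )
    assert len(results) == 2
    for key, run in results.items():
        assert not isinstance(run, Exception)
        assert set(dict(key)) == {"alpha", "eps_hb"}
        assert len(run.samples) > 0
    with pytest.raises(ValueError, match="unknown sweep parameter"):
        mc.sweep_parameters(cfg, system, tables, hp, {"bogus": [1]})
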