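"""Numba kernels for the Monte Carlo engine.

The system is small (<= 70 residues), so the engine recomputes the full
Hamiltonian at every Metropolis step instead of maintaining incremental
deltas; a full pass is ~1 microsecond compiled, and the approach removes a
whole class of bookkeeping bugs.  The kernels mirror
:mod:`amylattice.hamiltonian` term by term and are tested against it.

Array conventions (all chains concatenated, ``n`` residues per chain):

* ``pos``  (N, 3) int64 backbone sites, ``sdir`` (N,) int64 in [0, 6),
  ``beta`` (N,) int64 in {0, 1}
* ``occ``  (L, L, L) int64 occupancy grid holding residue index + 1
* ``scratch`` (L, L, L) int64 work grid for side-chain clash counting
* ``comp`` (11,) float64 energy components:
  [e_hb, e_steric, e_state, e_aa, e_solv_const, f_hydr_sum, e_hydr_sum,
   c_h_exposed (all chains), c_ext, total, c_h_exposed (free chains)]

RNG: xorshift128+ with one independent 2-word uint64 state per replica.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)

# component indices; C_H counts every exposed hydrophobic side chain (it
# drives the solvation energy), C_H_FREE only those on free chains (the
# order parameter of Eq-style analyses)
(
    E_HB,
    E_STERIC,
    E_STATE,
    E_AA,
    E_SOLV,
    F_HYDR,
    E_HYDR,
    C_H,
    C_EXT,
    TOTAL,
    C_H_FREE,
) = range(11)
N_COMPONENTS = 11

# move type codes (order fixed; weights supplied by the caller)
(
    MV_END,
    MV_CORNER,
    MV_CRANK,
    MV_TRANS,
    MV_ROT,
    MV_SIDE,
    MV_BETA,
    MV_SEED_TRANS,
    MV_SEED_ROT,
    MV_TELEPORT,
) = range(10)
N_MOVE_TYPES = 10


@njit(cache=False)
def rand_u(state):
    """xorshift128+ uniform in [0, 1)."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    state[1] = s1
    return float((s0 + s1) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=False)
def rand_int(state, bound):
    return int(rand_u(state) * bound)


@njit(cache=False)
def energy_components(
    pos,
    sdir,
    beta,
    occ,
    codes,
    hyd,
    n,
    n_seed_chains,
    eps_pair,
    eps_solv,
    eps_hb,
    ln_nbeta,
    steric_pen,
    alpha,
    t0,
    t,
    scratch,
    comp,
):
    """Full Hamiltonian pass; fills ``comp`` in place."""
    N = pos.shape[0]
    L = occ.shape[0]
    n_free_start = n_seed_chains * n
    hb_pairs = 0
    e_aa = 0.0
    c_ext = 0
    n_beta_res = 0
    e_solv = 0.0
    c_h = 0
    c_h_free = 0
    clashes = 0
    f_contact = -alpha * (t - t0) * (t - t0)
    e_contact = -alpha * (t0 * t0 - t * t)

    # backbone-adjacency terms over +x, +y, +z neighbours (unordered)
    for g in range(N):
        x = pos[g, 0]
        y = pos[g, 1]
        z = pos[g, 2]
        cg = g // n
        if beta[g] == 1:
            n_beta_res += 1
        for d in range(3):
            dd = 2 * d  # positive direction index 0, 2, 4
            qx = x + DIRS[dd, 0]
            qy = y + DIRS[dd, 1]
            qz = z + DIRS[dd, 2]
            if qx < 0 or qx >= L or qy < 0 or qy >= L or qz < 0 or qz >= L:
                continue
            h = occ[qx, qy, qz] - 1
            if h < 0:
                continue
            ch = h // n
            if cg != ch:
                if g >= n_free_start or h >= n_free_start:
                    c_ext += 1
                if (
                    beta[g] == 1
                    and beta[h] == 1
                    and sdir[g] == sdir[h]
                    and (
                        DIRS[sdir[g], 0] * DIRS[dd, 0]
                        + DIRS[sdir[g], 1] * DIRS[dd, 1]
                        + DIRS[sdir[g], 2] * DIRS[dd, 2]
                    )
                    == 0
                ):
                    hb_pairs += 1

    # side-chain terms: what each side chain points at determines its
    # interaction -- solvent (solvation + hydrophobic term), or a residue of
    # another molecule / non-adjacent residue (directed pair energy)
    for g in range(N):
        tx = pos[g, 0] + DIRS[sdir[g], 0]
        ty = pos[g, 1] + DIRS[sdir[g], 1]
        tz = pos[g, 2] + DIRS[sdir[g], 2]
        if tx < 0 or tx >= L or ty < 0 or ty >= L or tz < 0 or tz >= L:
            # beyond the hard wall counts as solvent; no clash possible there
            e_solv += eps_solv[codes[g]]
            if hyd[g] == 1:
                c_h += 1
                if g >= n_free_start:
                    c_h_free += 1
            continue
        h = occ[tx, ty, tz] - 1
        if h < 0:
            e_solv += eps_solv[codes[g]]
            if hyd[g] == 1:
                c_h += 1
                if g >= n_free_start:
                    c_h_free += 1
        else:
            cg = g // n
            if cg != h // n or (h - g != 1 and g - h != 1):
                e_aa += eps_pair[codes[g], codes[h]]
            else:
                # side chain crowding its own backbone neighbour
                clashes += 1
        scratch[tx, ty, tz] += 1

    for g in range(N):
        tx = pos[g, 0] + DIRS[sdir[g], 0]
        ty = pos[g, 1] + DIRS[sdir[g], 1]
        tz = pos[g, 2] + DIRS[sdir[g], 2]
        if tx < 0 or tx >= L or ty < 0 or ty >= L or tz < 0 or tz >= L:
            continue
        c = scratch[tx, ty, tz]
        if c > 0:
            clashes += c * (c - 1) // 2
            scratch[tx, ty, tz] = 0

    comp[E_HB] = eps_hb * hb_pairs
    comp[E_STERIC] = steric_pen * clashes
    comp[E_STATE] = ln_nbeta * n_beta_res
    comp[E_AA] = e_aa
    comp[E_SOLV] = e_solv
    comp[F_HYDR] = f_contact * c_h
    comp[E_HYDR] = e_contact * c_h
    comp[C_H] = c_h
    comp[C_EXT] = c_ext
    comp[TOTAL] = comp[E_HB] + comp[E_STERIC] + comp[E_STATE] + comp[E_AA] + comp[E_SOLV] + comp[F_HYDR]
    comp[C_H_FREE] = c_h_free


@njit(cache=False)
def native_contact_count(pos, variants):
    """Best native-contact count over the docking symmetry variants."""
    best = 0
    for v in range(variants.shape[0]):
        cnt = 0
        for p in range(variants.shape[1]):
            a = variants[v, p, 0]
            b = variants[v, p, 1]
            d = (
                abs(pos[a, 0] - pos[b, 0])
                + abs(pos[a, 1] - pos[b, 1])
                + abs(pos[a, 2] - pos[b, 2])
            )
            if d == 1:
                cnt += 1
        if cnt > best:
            best = cnt
    return best


@njit(cache=False)
def _rot_vec(vx, vy, vz, axis, k):
    """Rotate an integer vector by k*90 degrees about a coordinate axis."""
    for _ in range(k):
        if axis == 0:
            vy, vz = -vz, vy
        elif axis == 1:
            vx, vz = vz, -vx
        else:
            vx, vy = -vy, vx
    return vx, vy, vz


@njit(cache=False)
def _rot_dir(d, axis, k):
    vx, vy, vz = _rot_vec(DIRS[d, 0], DIRS[d, 1], DIRS[d, 2], axis, k)
    for j in range(6):
        if DIRS[j, 0] == vx and DIRS[j, 1] == vy and DIRS[j, 2] == vz:
            return j
    return d  # unreachable


@njit(cache=False)
def run_block(
    pos,
    sdir,
    beta,
    occ,
    codes,
    hyd,
    n,
    n_seed_chains,
    n_chains,
    eps_pair,
    eps_solv,
    eps_hb,
    ln_nbeta,
    steric_pen,
    alpha,
    t0,
    t,
    n_steps,
    rng,
    move_cum,
    scratch,
    comp,
    move_attempts,
    move_accepts,
):
    """Run ``n_steps`` Metropolis steps at temperature ``t``.

    ``comp`` must hold the current energy components on entry and holds them
    on exit.  ``move_cum`` is the cumulative probability over the 10 move
    types.  ``move_attempts``/``move_accepts`` (length 10) accumulate
    statistics.  Returns the number of accepted moves.
    """
    N = pos.shape[0]
    L = occ.shape[0]
    n_free = n_chains - n_seed_chains
    n_seed_res = n_seed_chains * n
    comp_new = np.empty(N_COMPONENTS, dtype=np.float64)
    # undo buffers
    old_pos = np.empty((N, 3), dtype=np.int64)
    old_sdir = np.empty(N, dtype=np.int64)
    moved = np.empty(N, dtype=np.int64)
    accepted_total = 0

    for _step in range(n_steps):
        u = rand_u(rng)
        mv = 0
        while mv < N_MOVE_TYPES - 1 and u > move_cum[mv]:
            mv += 1
        move_attempts[mv] += 1

        n_moved = 0
        beta_flip_res = -1
        valid = True

        if mv == MV_BETA:
            g = n_seed_res + rand_int(rng, n_free * n)
            beta[g] = 1 - beta[g]
            beta_flip_res = g
        elif mv == MV_SIDE:
            g = n_seed_res + rand_int(rng, n_free * n)
            moved[0] = g
            old_sdir[0] = sdir[g]
            old_pos[0, 0] = pos[g, 0]
            old_pos[0, 1] = pos[g, 1]
            old_pos[0, 2] = pos[g, 2]
            n_moved = 1
            sdir[g] = rand_int(rng, 6)
        else:
            # position moves: gather the moved residue set, then apply
            if mv == MV_END or mv == MV_CORNER or mv == MV_CRANK:
                c = n_seed_chains + rand_int(rng, n_free)
                base = c * n
                if mv == MV_END:
                    end = 0 if rand_u(rng) < 0.5 else n - 1
                    g = base + end
                    anchor = base + (1 if end == 0 else n - 2)
                    d = rand_int(rng, 6)
                    nx = pos[anchor, 0] + DIRS[d, 0]
                    ny = pos[anchor, 1] + DIRS[d, 1]
                    nz = pos[anchor, 2] + DIRS[d, 2]
                    moved[0] = g
                    n_moved = 1
                    old_pos[0, 0] = pos[g, 0]
                    old_pos[0, 1] = pos[g, 1]
                    old_pos[0, 2] = pos[g, 2]
                    old_sdir[0] = sdir[g]
                    occ[pos[g, 0], pos[g, 1], pos[g, 2]] = 0
                    if (
                        nx < 0
                        or nx >= L
                        or ny < 0
                        or ny >= L
                        or nz < 0
                        or nz >= L
                        or occ[nx, ny, nz] != 0
                    ):
                        valid = False
                    else:
                        pos[g, 0] = nx
                        pos[g, 1] = ny
                        pos[g, 2] = nz
                elif mv == MV_CORNER:
                    i = 1 + rand_int(rng, n - 2)
                    g = base + i
                    ax = pos[g - 1, 0] - pos[g, 0]
                    ay = pos[g - 1, 1] - pos[g, 1]
                    az = pos[g - 1, 2] - pos[g, 2]
                    bx = pos[g + 1, 0] - pos[g, 0]
                    by = pos[g + 1, 1] - pos[g, 1]
                    bz = pos[g + 1, 2] - pos[g, 2]
                    if ax * bx + ay * by + az * bz != 0:
                        valid = False  # straight segment: no corner to flip
                        n_moved = 0
                    else:
                        nx = pos[g - 1, 0] + bx
                        ny = pos[g - 1, 1] + by
                        nz = pos[g - 1, 2] + bz
                        moved[0] = g
                        n_moved = 1
                        old_pos[0, 0] = pos[g, 0]
                        old_pos[0, 1] = pos[g, 1]
                        old_pos[0, 2] = pos[g, 2]
                        old_sdir[0] = sdir[g]
                        occ[pos[g, 0], pos[g, 1], pos[g, 2]] = 0
                        if (
                            nx < 0
                            or nx >= L
                            or ny < 0
                            or ny >= L
                            or nz < 0
                            or nz >= L
                            or occ[nx, ny, nz] != 0
                        ):
                            valid = False
                        else:
                            pos[g, 0] = nx
                            pos[g, 1] = ny
                            pos[g, 2] = nz
                else:  # crankshaft on residues i+1, i+2 about axis (i, i+3)
                    if n < 4:
                        valid = False
                        n_moved = 0
                    else:
                        i = rand_int(rng, n - 3)
                        g0 = base + i
                        dx = pos[g0 + 3, 0] - pos[g0, 0]
                        dy = pos[g0 + 3, 1] - pos[g0, 1]
                        dz = pos[g0 + 3, 2] - pos[g0, 2]
                        if abs(dx) + abs(dy) + abs(dz) != 1:
                            valid = False
                            n_moved = 0
                        else:
                            axis = 0 if dx != 0 else (1 if dy != 0 else 2)
                            k = 1 + rand_int(rng, 3)
                            n_moved = 2
                            for j in range(2):
                                g = g0 + 1 + j
                                moved[j] = g
                                old_pos[j, 0] = pos[g, 0]
                                old_pos[j, 1] = pos[g, 1]
                                old_pos[j, 2] = pos[g, 2]
                                old_sdir[j] = sdir[g]
                                occ[pos[g, 0], pos[g, 1], pos[g, 2]] = 0
                            for j in range(2):
                                g = g0 + 1 + j
                                vx = old_pos[j, 0] - pos[g0, 0]
                                vy = old_pos[j, 1] - pos[g0, 1]
                                vz = old_pos[j, 2] - pos[g0, 2]
                                vx, vy, vz = _rot_vec(vx, vy, vz, axis, k)
                                nx = pos[g0, 0] + vx
                                ny = pos[g0, 1] + vy
                                nz = pos[g0, 2] + vz
                                if (
                                    nx < 0
                                    or nx >= L
                                    or ny < 0
                                    or ny >= L
                                    or nz < 0
                                    or nz >= L
                                    or occ[nx, ny, nz] != 0
                                ):
                                    valid = False
                                    # clear any bead already placed at its new site
                                    for j2 in range(j):
                                        g2 = g0 + 1 + j2
                                        occ[pos[g2, 0], pos[g2, 1], pos[g2, 2]] = 0
                                    break
                                pos[g, 0] = nx
                                pos[g, 1] = ny
                                pos[g, 2] = nz
                                sdir[g] = _rot_dir(old_sdir[j], axis, k)
                                occ[nx, ny, nz] = g + 1
                            if valid:
                                # remove again for the generic re-occupation below
                                for j in range(2):
                                    g = g0 + 1 + j
                                    occ[pos[g, 0], pos[g, 1], pos[g, 2]] = 0
            else:
                # rigid-body moves: whole free chain or the whole seed
                if mv == MV_SEED_TRANS or mv == MV_SEED_ROT:
                    first = 0
                    last = n_seed_res
                else:
                    c = n_seed_chains + rand_int(rng, n_free)
                    first = c * n
                    last = first + n
                n_moved = last - first
                for j in range(n_moved):
                    g = first + j
                    moved[j] = g
                    old_pos[j, 0] = pos[g, 0]
                    old_pos[j, 1] = pos[g, 1]
                    old_pos[j, 2] = pos[g, 2]
                    old_sdir[j] = sdir[g]
                    occ[pos[g, 0], pos[g, 1], pos[g, 2]] = 0
                if mv == MV_TRANS or mv == MV_SEED_TRANS:
                    d = rand_int(rng, 6)
                    for j in range(n_moved):
                        g = first + j
                        pos[g, 0] += DIRS[d, 0]
                        pos[g, 1] += DIRS[d, 1]
                        pos[g, 2] += DIRS[d, 2]
                elif mv == MV_TELEPORT:
                    span = 2 * L - 1
                    tx = rand_int(rng, span) - (L - 1)
                    ty = rand_int(rng, span) - (L - 1)
                    tz = rand_int(rng, span) - (L - 1)
                    for j in range(n_moved):
                        g = first + j
                        pos[g, 0] += tx
                        pos[g, 1] += ty
                        pos[g, 2] += tz
                else:  # MV_ROT or MV_SEED_ROT: 90/180/270 about a random axis
                    axis = rand_int(rng, 3)
                    k = 1 + rand_int(rng, 3)
                    pivot = first + rand_int(rng, n_moved)
                    px = old_pos[pivot - first, 0]
                    py = old_pos[pivot - first, 1]
                    pz = old_pos[pivot - first, 2]
                    for j in range(n_moved):
                        g = first + j
                        vx, vy, vz = _rot_vec(
                            old_pos[j, 0] - px,
                            old_pos[j, 1] - py,
                            old_pos[j, 2] - pz,
                            axis,
                            k,
                        )
                        pos[g, 0] = px + vx
                        pos[g, 1] = py + vy
                        pos[g, 2] = pz + vz
                        sdir[g] = _rot_dir(old_sdir[j], axis, k)
                # bounds / overlap check against the rest of the system
                for j in range(n_moved):
                    g = first + j
                    if (
                        pos[g, 0] < 0
                        or pos[g, 0] >= L
                        or pos[g, 1] < 0
                        or pos[g, 1] >= L
                        or pos[g, 2] < 0
                        or pos[g, 2] >= L
                        or occ[pos[g, 0], pos[g, 1], pos[g, 2]] != 0
                    ):
                        valid = False
                        break

        if mv != MV_BETA and mv != MV_SIDE and n_moved > 0:
            if valid:
                # re-occupy new sites, checking for collisions among the
                # moved residues themselves
                for j in range(n_moved):
                    g = moved[j]
                    if occ[pos[g, 0], pos[g, 1], pos[g, 2]] != 0:
                        valid = False
                        # roll back the ones already written
                        for j2 in range(j):
                            g2 = moved[j2]
                            occ[pos[g2, 0], pos[g2, 1], pos[g2, 2]] = 0
                        break
                    occ[pos[g, 0], pos[g, 1], pos[g, 2]] = g + 1
            if not valid:
                for j in range(n_moved):
                    g = moved[j]
                    pos[g, 0] = old_pos[j, 0]
                    pos[g, 1] = old_pos[j, 1]
                    pos[g, 2] = old_pos[j, 2]
                    sdir[g] = old_sdir[j]
                    occ[pos[g, 0], pos[g, 1], pos[g, 2]] = g + 1
                continue
        if not valid:
            continue

        energy_components(
            pos,
            sdir,
            beta,
            occ,
            codes,
            hyd,
            n,
            n_seed_chains,
            eps_pair,
            eps_solv,
            eps_hb,
            ln_nbeta,
            steric_pen,
            alpha,
            t0,
            t,
            scratch,
            comp_new,
        )
        delta = comp_new[TOTAL] - comp[TOTAL]
        accept = delta <= 0.0 or rand_u(rng) < np.exp(-delta / t)
        if accept:
            for j in range(N_COMPONENTS):
                comp[j] = comp_new[j]
            accepted_total += 1
            move_accepts[mv] += 1
        else:
            if beta_flip_res >= 0:
                beta[beta_flip_res] = 1 - beta[beta_flip_res]
            elif mv == MV_SIDE:
                sdir[moved[0]] = old_sdir[0]
            else:
                for j in range(n_moved):
                    g = moved[j]
                    occ[pos[g, 0], pos[g, 1], pos[g, 2]] = 0
                for j in range(n_moved):
                    g = moved[j]
                    pos[g, 0] = old_pos[j, 0]
                    pos[g, 1] = old_pos[j, 1]
                    pos[g, 2] = old_pos[j, 2]
                    sdir[g] = old_sdir[j]
                    occ[pos[g, 0], pos[g, 1], pos[g, 2]] = g + 1
    return accepted_total
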