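"""Trajectory analysis: states, landscapes, elongation thermodynamics.

The sampled ensemble is classified into the four states of the elongation
equilibrium -- monomeric, amorphous, fibrillar and fully aggregated -- from
the order parameters (external contacts, native-contact fraction, exposed
hydrophobic side chains).  From classified samples the module computes
free-energy landscapes over order-parameter pairs, the elongation curves
dG(T), dE(T), -T dS(T) between the fibrillar and monomeric states, the heat
capacity of elongation (the temperature slope of dE), and state diagrams
over parameter sweeps.

Free-energy scale: dG = 0 corresponds to equal visitation of the fibrillar
and monomeric states at the simulation's nominal monomer concentration
(2 chains in the box; about 4.6 mM for a ~4.5 Angstrom lattice spacing).
Experimental free-energy scales are referenced to much higher critical
concentrations, so absolute values differ by several k_B T and only the
temperature dependence should be compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .thermo import ThermoTriple

__all__ = [
    "StateLabel",
    "StateThresholds",
    "classify_state",
    "classify_samples",
    "free_energy_landscape",
    "ThermoCurve",
    "elongation_curves",
    "heat_capacity",
    "StateDiagram",
    "state_diagram",
    "fibril_window",
    "cold_monomeric_temperature",
]


class StateLabel(str, Enum):
    MONOMERIC = "monomeric"
    AMORPHOUS = "amorphous"
    FIBRILLAR = "fibrillar"
    FULLY_AGGREGATED = "fully_aggregated"


@dataclass(frozen=True)
class StateThresholds:
    """Configurable state definitions.

    ``monomeric``: no more than ``mono_max_cext`` external contacts.
    ``fibrillar``: at least ``fib_native`` of the reference contacts present
    *and* a formed hydrophobic core (at most ``core_max_exposed`` exposed
    hydrophobic side chains) -- the core condition distinguishes the fibril
    from the cold, attached-but-everted aggregate, and the native threshold
    tolerates frayed chain ends.  ``fully_aggregated``: the complete docked
    layer (all external contacts, near-perfect registry, formed core).
    """

    mono_max_cext: int = 1
    fib_native: float = 2 / 3
    full_native: float = 18 / 21
    full_cext: int = 21
    core_max_exposed: int = 1


DEFAULT_THRESHOLDS = StateThresholds()


def classify_state(order_params, thresholds: StateThresholds = DEFAULT_THRESHOLDS) -> StateLabel:
    """Classify one configuration by its order parameters.

    ``order_params`` needs attributes ``c_ext``, ``native_fraction`` and
    ``c_h_exposed`` (an :class:`~amylattice.lattice.OrderParams`, a sample
    row, or any namespace).
    """
    c_ext = order_params.c_ext
    native = order_params.native_fraction
    c_h = order_params.c_h_exposed
    if c_ext <= thresholds.mono_max_cext:
        return StateLabel.MONOMERIC
    if c_h <= thresholds.core_max_exposed:
        if c_ext >= thresholds.full_cext and native >= thresholds.full_native:
            return StateLabel.FULLY_AGGREGATED
        if native >= thresholds.fib_native:
            return StateLabel.FIBRILLAR
    return StateLabel.AMORPHOUS


def classify_samples(
    samples: pd.DataFrame, thresholds: StateThresholds = DEFAULT_THRESHOLDS
) -> pd.Series:
    """Vectorised :func:`classify_state` over a sample DataFrame."""
    mono = samples["c_ext"] <= thresholds.mono_max_cext
    core = samples["c_h_exposed"] <= thresholds.core_max_exposed
    full = core & (samples["c_ext"] >= thresholds.full_cext) & (
        samples["native_fraction"] >= thresholds.full_native
    )
    fib = core & (samples["native_fraction"] >= thresholds.fib_native)
    out = pd.Series(StateLabel.AMORPHOUS.value, index=samples.index, dtype=object)
    out[fib] = StateLabel.FIBRILLAR.value
    out[full] = StateLabel.FULLY_AGGREGATED.value
    out[mono] = StateLabel.MONOMERIC.value
    return out


def free_energy_landscape(
    samples: pd.DataFrame,
    t: float,
    axes: Tuple[str, str] = ("c_ext", "c_h_exposed"),
    bins: Tuple[int, int] | Tuple[np.ndarray, np.ndarray] = (22, 7),
):
    """Binned free-energy surface F = -T ln P over two order parameters.

    Returns ``(F, x_edges, y_edges)``; unvisited bins are NaN and the
    global minimum is shifted to zero.
    """
    if len(samples) == 0:
        raise ValueError("no samples to histogram")
    x = samples[axes[0]].to_numpy(dtype=float)
    y = samples[axes[1]].to_numpy(dtype=float)
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    if counts.sum() == 0:
        raise ValueError("all-empty histogram")
    with np.errstate(divide="ignore"):
        f = -t * np.log(counts / counts.sum())
    f[counts == 0] = np.nan
    f -= np.nanmin(f)
    return f, xe, ye


@dataclass
class ThermoCurve:
    """Elongation thermodynamics on a temperature grid.

    ``delta_g = delta_e + minus_t_delta_s`` holds per point by construction.
    ``sampled`` flags temperatures where both reference states were visited
    at least ``min_visits`` times; the other rows carry NaN values rather
    than interpolations.  ``estimate_overlay`` optionally carries the
    closed-form hydrophobic estimates evaluated on the same grid.
    """

    temperatures: np.ndarray
    delta_g: np.ndarray
    delta_e: np.ndarray
    minus_t_delta_s: np.ndarray
    delta_g_err: np.ndarray
    delta_e_err: np.ndarray
    sampled: np.ndarray
    n_fib: np.ndarray
    n_mono: np.ndarray
    estimate_overlay: Optional[ThermoTriple] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature": self.temperatures,
                "delta_g": self.delta_g,
                "delta_e": self.delta_e,
                "minus_t_delta_s": self.minus_t_delta_s,
                "delta_g_err": self.delta_g_err,
                "delta_e_err": self.delta_e_err,
                "sampled": self.sampled,
                "n_fib": self.n_fib,
                "n_mono": self.n_mono,
            }
        )


def _block_means(values: np.ndarray, n_blocks: int) -> np.ndarray:
    blocks = np.array_split(values, n_blocks)
    return np.array([b.mean() for b in blocks if len(b)])


def elongation_curves(
    samples: pd.DataFrame,
    thresholds: StateThresholds = DEFAULT_THRESHOLDS,
    min_visits: int = 50,
    n_blocks: int = 20,
    fib_label: Iterable[StateLabel] = (StateLabel.FIBRILLAR, StateLabel.FULLY_AGGREGATED),
    labels: Optional[pd.Series] = None,
) -> ThermoCurve:
    """Per-temperature elongation thermodynamics from classified samples.

    dG(T) = -T ln(P_fib / P_mono) from visitation ratios; dE(T) is the
    difference of conditional means of the enthalpy estimator between the
    fibrillar and monomeric states; -T dS = dG - dE.  Errors are block
    averages over ``n_blocks`` blocks of the time series.  Temperatures at
    which either state was visited fewer than ``min_visits`` times are
    flagged unsampled and reported as NaN (never interpolated).

    ``labels`` may supply a precomputed per-sample state series (same index
    as ``samples``), e.g. for toy systems with bespoke state definitions.
    """
    fib_values = {l.value for l in fib_label}
    if labels is None:
        labels = classify_samples(samples, thresholds)
    temps = np.array(sorted(samples["temperature"].unique()))
    n_t = len(temps)
    out = {
        k: np.full(n_t, np.nan)
        for k in ("dg", "de", "dg_err", "de_err")
    }
    sampled = np.zeros(n_t, dtype=bool)
    n_fib = np.zeros(n_t, dtype=int)
    n_mono = np.zeros(n_t, dtype=int)
    for i, t in enumerate(temps):
        sel = np.isclose(samples["temperature"], t)
        sub = samples[sel].sort_values("sweep")
        lab = labels[sel].reindex(sub.index)
        is_fib = lab.isin(fib_values).to_numpy()
        is_mono = (lab == StateLabel.MONOMERIC.value).to_numpy()
        n_fib[i] = int(is_fib.sum())
        n_mono[i] = int(is_mono.sum())
        if n_fib[i] < min_visits or n_mono[i] < min_visits:
            continue
        sampled[i] = True
        est = sub["enthalpy_est"].to_numpy()
        p_fib, p_mono = is_fib.mean(), is_mono.mean()
        out["dg"][i] = -t * np.log(p_fib / p_mono)
        out["de"][i] = est[is_fib].mean() - est[is_mono].mean()
        # block averaging for error bars
        bf = _block_means(is_fib.astype(float), n_blocks)
        bm = _block_means(is_mono.astype(float), n_blocks)
        ok = (bf > 0) & (bm > 0)
        if ok.sum() >= 2:
            dg_blocks = -t * np.log(bf[ok] / bm[ok])
            out["dg_err"][i] = dg_blocks.std(ddof=1) / np.sqrt(ok.sum())
        # per-block conditional means (blocks lacking a state are dropped)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            blocks_f = [np.nanmean(b) for b in np.array_split(np.where(is_fib, est, np.nan), n_blocks)]
            blocks_m = [np.nanmean(b) for b in np.array_split(np.where(is_mono, est, np.nan), n_blocks)]
        de_blocks = np.array(
            [f - m for f, m in zip(blocks_f, blocks_m) if np.isfinite(f) and np.isfinite(m)]
        )
        if len(de_blocks) >= 2:
            out["de_err"][i] = de_blocks.std(ddof=1) / np.sqrt(len(de_blocks))
    return ThermoCurve(
        temperatures=temps,
        delta_g=out["dg"],
        delta_e=out["de"],
        minus_t_delta_s=out["dg"] - out["de"],
        delta_g_err=out["dg_err"],
        delta_e_err=out["de_err"],
        sampled=sampled,
        n_fib=n_fib,
        n_mono=n_mono,
    )


def heat_capacity(curve: ThermoCurve) -> pd.DataFrame:
    """Centred finite-difference slope of dE versus T (the heat capacity of
    elongation), with propagated uncertainties.  Requires >= 3 sampled
    temperatures."""
    t = curve.temperatures[curve.sampled]
    de = curve.delta_e[curve.sampled]
    err = curve.delta_e_err[curve.sampled]
    if len(t) < 3:
        raise ValueError("need at least 3 sampled temperatures for a slope")
    mid_t = t[1:-1]
    dt = t[2:] - t[:-2]
    slope = (de[2:] - de[:-2]) / dt
    slope_err = np.sqrt(err[2:] ** 2 + err[:-2] ** 2) / dt
    return pd.DataFrame(
        {"temperature": mid_t, "dcp": slope, "dcp_err": slope_err}
    )


@dataclass
class StateDiagram:
    """Dominant state per (parameter value, temperature) cell.

    ``table`` has columns parameter, temperature, state, sampled, and the
    per-state fractions.  Unsampled cells are flagged, never interpolated.
    """

    parameter: str
    table: pd.DataFrame

    def dominant(self, value, temperature) -> str:
        row = self.table[
            np.isclose(self.table["parameter_value"], value)
            & np.isclose(self.table["temperature"], temperature)
        ]
        return row["state"].iloc[0] if len(row) else "unsampled"


def state_diagram(
    runs: Dict[float, pd.DataFrame],
    parameter: str = "alpha",
    thresholds: StateThresholds = DEFAULT_THRESHOLDS,
    min_samples: int = 20,
) -> StateDiagram:
    """Modal state per parameter-value / temperature cell.

    ``runs`` maps parameter values to sample DataFrames (from
    :func:`amylattice.mc.run_elongation`).
    """
    rows = []
    for value, samples in runs.items():
        labels = classify_samples(samples, thresholds)
        for t, idx in samples.groupby("temperature").groups.items():
            lab = labels.loc[idx]
            counts = lab.value_counts()
            sampled = len(lab) >= min_samples
            rows.append(
                {
                    "parameter_value": value,
                    "temperature": t,
                    "state": counts.idxmax() if sampled else "unsampled",
                    "sampled": sampled,
                    **{
                        s.value: float((lab == s.value).mean())
                        for s in StateLabel
                    },
                }
            )
    return StateDiagram(parameter=parameter, table=pd.DataFrame(rows))


def _fib_like(state: str) -> bool:
    return state in (StateLabel.FIBRILLAR.value, StateLabel.FULLY_AGGREGATED.value)


def fibril_window(diagram: StateDiagram, value) -> Tuple[float, float] | None:
    """Temperature range over which the fibrillar state is dominant."""
    sub = diagram.table[
        np.isclose(diagram.table["parameter_value"], value)
    ].sort_values("temperature")
    fib_temps = sub.loc[sub["state"].map(_fib_like), "temperature"].to_numpy()
    if len(fib_temps) == 0:
        return None
    return float(fib_temps.min()), float(fib_temps.max())


def cold_monomeric_temperature(diagram: StateDiagram, value) -> Optional[float]:
    """Highest temperature below the fibrillar stability window at which the
    monomeric state dominates (the cold-denaturation readout); None when the
    window or a monomeric cell below it is absent."""
    window = fibril_window(diagram, value)
    if window is None:
        return None
    sub = diagram.table[
        np.isclose(diagram.table["parameter_value"], value)
    ].sort_values("temperature")
    below = sub[
        (sub["temperature"] < window[0])
        & (sub["state"] == StateLabel.MONOMERIC.value)
    ]
    if len(below) == 0:
        return None
    return float(below["temperature"].max())
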