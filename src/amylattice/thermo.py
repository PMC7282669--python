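"""Closed-form thermodynamics of the temperature-dependent hydrophobic effect.

The solvation free energy of an exposed hydrophobic side chain is modelled as

    F_hydr(T) = -alpha * C_h * (T - T0)**2

which is maximally favourable at ``T0`` and weakens both on cooling and on
heating.  Because ``F_hydr`` depends on temperature it is *not* the enthalpy;
the enthalpy follows from the Gibbs-Helmholtz relation
``E = d(beta*F)/d(beta)`` (beta = 1/T, k_B = 1):

    E_hydr(T)   = -alpha * C_h * (T0**2 - T**2)
    -T*S_hydr(T) = F_hydr - E_hydr

These three relations, and the elongation-level estimates built from them
(``DeltaH(T) = gamma*(T0**2 - T**2) + E_int`` with ``gamma = alpha*|dC_h|``),
are shared by the lattice simulator, the landscape analysis and the
calorimetry fitting tools.

Two unit systems are supported by the same formulas: reduced units
(k_B = 1, simulation mode, T0 = 0.4) and physical units
(kJ/mol and Kelvin, experimental mode, T0 = 343.15 K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "GAS_CONSTANT_KJ",
    "HydrophobicParams",
    "ThermoTriple",
    "ElongationEstimateParams",
    "f_hydr",
    "e_hydr",
    "minus_t_s_hydr",
    "estimate_elongation",
    "crossover_temperature",
]

#: Gas constant in kJ/(mol K), used whenever physical units are in play.
GAS_CONSTANT_KJ = 8.314e-3


@dataclass(frozen=True)
class HydrophobicParams:
    """Strength and optimum temperature of the hydrophobic effect.

    Parameters
    ----------
    alpha:
        Strength of the hydrophobic temperature dependence, per exposed
        contact.  Reduced energy per reduced T**2 in simulation mode, or
        kJ/(mol K**2 contact) in physical mode.  Must be >= 0.
    t0:
        Temperature of the maximal hydrophobic effect (reduced units or
        Kelvin).  Must be > 0.
    """

    alpha: float
    t0: float = 0.4

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.t0 <= 0:
            raise ValueError(f"t0 must be > 0, got {self.t0}")


@dataclass(frozen=True)
class ThermoTriple:
    """Free energy, enthalpy and entropic term of one event, per grid point.

    The exact identity ``free_energy = enthalpy + minus_t_entropy`` holds
    element-wise by construction.
    """

    free_energy: np.ndarray
    enthalpy: np.ndarray
    minus_t_entropy: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.free_energy, dtype=float)
        e = np.asarray(self.enthalpy, dtype=float)
        ts = np.asarray(self.minus_t_entropy, dtype=float)
        if not (g.shape == e.shape == ts.shape):
            raise ValueError("ThermoTriple components must share a shape")
        object.__setattr__(self, "free_energy", g)
        object.__setattr__(self, "enthalpy", e)
        object.__setattr__(self, "minus_t_entropy", ts)


@dataclass(frozen=True)
class ElongationEstimateParams:
    """Parameters of the analytic elongation estimates.

    ``gamma`` is the effective hydrophobic strength of the elongation step:
    ``gamma = alpha * |dC_h|`` in the lattice model (dC_h = change in exposed
    hydrophobic contacts on docking, -6 for the default peptide), or
    ``gamma = alpha * A_h`` in the per-surface-area reading used for real
    fibrils.  ``gamma >= 0`` corresponds to burial-driven assembly, i.e. an
    elongation enthalpy that decreases with temperature (negative heat
    capacity).  ``e_int`` is the temperature-independent internal-energy
    offset of elongation.
    """

    gamma: float
    e_int: float
    t0: float = 0.4

    def __post_init__(self) -> None:
        if not math.isfinite(self.gamma):
            raise ValueError("gamma must be finite")
        if self.t0 <= 0:
            raise ValueError(f"t0 must be > 0, got {self.t0}")


def _check_temperature(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be strictly positive")
    return t


def f_hydr(params: HydrophobicParams, c_h, t):
    """Hydrophobic free energy of ``c_h`` exposed contacts at temperature ``t``.

    Returns ``-alpha * c_h * (t - t0)**2``; always <= 0, with equality exactly
    at ``t == t0`` or ``c_h == 0``.
    """
    t = _check_temperature(t)
    c_h = np.asarray(c_h, dtype=float)
    if np.any(c_h < 0):
        raise ValueError("c_h must be >= 0")
    out = -params.alpha * c_h * (t - params.t0) ** 2
    return out if out.ndim else float(out)


def e_hydr(params: HydrophobicParams, c_h, t):
    """Hydrophobic enthalpy, the beta-derivative of ``beta * f_hydr``.

    Analytically ``d(beta*F)/d(beta) = -alpha * c_h * (t0**2 - t**2)``.
    """
    t = _check_temperature(t)
    c_h = np.asarray(c_h, dtype=float)
    if np.any(c_h < 0):
        raise ValueError("c_h must be >= 0")
    out = -params.alpha * c_h * (params.t0 ** 2 - t ** 2)
    return out if out.ndim else float(out)


def minus_t_s_hydr(params: HydrophobicParams, c_h, t):
    """Entropic term ``-T*S_hydr = F_hydr - E_hydr``."""
    return f_hydr(params, c_h, t) - e_hydr(params, c_h, t)


def estimate_elongation(params: ElongationEstimateParams, t_grid) -> ThermoTriple:
    """Analytic estimates of elongation thermodynamics on a temperature grid.

    With ``gamma = alpha * |dC_h|`` for the net burial of ``|dC_h|`` exposed
    hydrophobic contacts (dC_h < 0 on docking):

        DeltaH(t) = gamma * (t0**2 - t**2) + e_int
        DeltaG(t) = gamma * (t - t0)**2   + e_int
        -T*DeltaS(t) = DeltaG(t) - DeltaH(t)

    The free-energy sign follows from applying the per-contact
    ``F_hydr = -alpha (t-t0)**2`` to the *loss* of ``|dC_h|`` exposed
    contacts: the fibril is maximally stabilised at ``t0`` and destabilised
    both on cooling and heating, which is what produces cold and heat
    denaturation in the full model.
    """
    t = np.atleast_1d(_check_temperature(t_grid)) if np.size(t_grid) else np.empty(0)
    enthalpy = params.gamma * (params.t0 ** 2 - t ** 2) + params.e_int
    free_energy = params.gamma * (t - params.t0) ** 2 + params.e_int
    return ThermoTriple(
        free_energy=free_energy,
        enthalpy=enthalpy,
        minus_t_entropy=free_energy - enthalpy,
    )


def crossover_temperature(params: ElongationEstimateParams) -> Optional[float]:
    """Temperature at which the estimated elongation enthalpy changes sign.

    Solves ``gamma*(t0**2 - t**2) + e_int = 0`` for t > 0:
    ``T_x = sqrt(t0**2 + e_int/gamma)``.  For ``e_int < 0`` elongation is
    endothermic below ``T_x`` and exothermic above it.  Returns ``None``
    when no real positive root exists (enthalpy never changes sign).
    """
    if params.gamma <= 0:
        raise ValueError("no crossover defined for gamma <= 0")
    disc = params.t0 ** 2 + params.e_int / params.gamma
    if disc <= 0:
        return None
    return math.sqrt(disc)
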