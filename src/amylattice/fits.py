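"""Fitting tools for calorimetry, depolymerisation and the surface-area
meta-analysis.

Three procedures, all in physical units (kJ/mol, Kelvin, molar):

* **Elongation enthalpy vs temperature.**  ITC-style molar enthalpies
  dH(T) are fitted to the hydrophobic form ``dH(T) = gamma (T0^2 - T^2) +
  E_int`` with ``T0 = 343.15 K`` fixed -- linear in (gamma, E_int), solved
  by (weighted) least squares.  The fit implies a heat capacity
  ``dCp(T) = -2 gamma T``, negative for gamma > 0.

* **Isodesmic chemical depolymerisation.**  The fraction of free monomer
  at total concentration [M]_T and denaturant concentration [D] follows the
  isodesmic (single equilibrium constant) linear-polymerisation solution
  ``y = (2x + 1 - sqrt(4x + 1)) / (2 x^2)`` with ``x = K [M]_T`` and
  ``K = exp(-(dG0 + m [D]) / RT)`` (1 M standard state).  (dG0, m) are
  recovered by nonlinear least squares.

* **gamma versus buried hydrophobic surface area.**  A_h sums the maximal
  solvent-accessible areas of the hydrophobic residues (C F L W V I M Y A)
  of the fibril-core sequence region; fitted gammas are regressed on A_h
  through the origin to give the per-area strength of the hydrophobic
  effect.

Synthetic-data generators for both experiment types support parameter
recovery validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence as TypingSequence

import numpy as np
from scipy.optimize import curve_fit

from .hamiltonian import _data_path
from .lattice import AA_INDEX, HYDROPHOBIC_RESIDUES, Sequence
from .thermo import GAS_CONSTANT_KJ, ElongationEstimateParams

__all__ = [
    "T0_EXPERIMENTAL_K",
    "ITCCurve",
    "EnthalpyFit",
    "DepolymerisationCurve",
    "IsodesmicFit",
    "AreaRecord",
    "fit_enthalpy_vs_temperature",
    "isodesmic_fraction",
    "fit_isodesmic",
    "load_area_table",
    "hydrophobic_area",
    "fit_gamma_vs_area",
    "generate_synthetic_itc",
    "generate_synthetic_depoly",
]

#: Temperature of the maximal hydrophobic effect used in experimental fits.
T0_EXPERIMENTAL_K = 343.15


@dataclass(frozen=True)
class ITCCurve:
    """Molar elongation enthalpies versus temperature.

    ``delta_h`` holds per-injection heats already normalised per mole of
    reacted monomer (kJ/mol); ``sigma`` optional per-point uncertainties.
    """

    temperatures: np.ndarray  # K
    delta_h: np.ndarray  # kJ/mol
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        dh = np.asarray(self.delta_h, dtype=float)
        if t.shape != dh.shape or t.ndim != 1:
            raise ValueError("temperatures and delta_h must be matching 1-d arrays")
        if len(np.unique(t)) != len(t):
            raise ValueError("temperatures must be distinct")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "delta_h", dh)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != t.shape or np.any(s <= 0):
                raise ValueError("sigma must be positive and match temperatures")
            object.__setattr__(self, "sigma", s)


@dataclass(frozen=True)
class EnthalpyFit:
    """Result of the hydrophobic enthalpy fit.

    ``gamma`` in kJ/(mol K^2); ``e_int`` in kJ/mol; ``covariance`` of
    (gamma, e_int).  ``delta_cp(T) = -2 gamma T`` has the opposite sign to
    gamma.
    """

    gamma: float
    e_int: float
    t0: float
    covariance: np.ndarray

    @property
    def gamma_err(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def e_int_err(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    def delta_cp(self, t) -> np.ndarray:
        return -2.0 * self.gamma * np.asarray(t, dtype=float)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.gamma * (self.t0 ** 2 - t ** 2) + self.e_int

    def as_estimate_params(self) -> ElongationEstimateParams:
        return ElongationEstimateParams(gamma=self.gamma, e_int=self.e_int, t0=self.t0)


def fit_enthalpy_vs_temperature(
    curve: ITCCurve, t0: float = T0_EXPERIMENTAL_K
) -> EnthalpyFit:
    """Least-squares fit of dH(T) = gamma (t0^2 - T^2) + E_int.

    Linear in (gamma, E_int) with basis {(t0^2 - T^2), 1}; solved by the
    normal equations (weighted when per-point sigmas are provided).
    """
    t = curve.temperatures
    if len(t) < 3:
        raise ValueError("need at least 3 temperatures to fit")
    basis = np.column_stack([t0 ** 2 - t ** 2, np.ones_like(t)])
    y = curve.delta_h
    if curve.sigma is not None:
        w = 1.0 / curve.sigma
        basis = basis * w[:, None]
        y = y * w
    if np.linalg.matrix_rank(basis) < 2:
        raise ValueError("degenerate design (all temperatures equal?)")
    coef, residuals, *_ = np.linalg.lstsq(basis, y, rcond=None)
    dof = max(len(t) - 2, 1)
    resid = y - basis @ coef
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(basis.T @ basis)
    return EnthalpyFit(gamma=float(coef[0]), e_int=float(coef[1]), t0=t0, covariance=cov)


@dataclass(frozen=True)
class DepolymerisationCurve:
    """Monomer fraction versus denaturant at fixed total concentration."""

    denaturant: np.ndarray  # M
    fraction_monomer: np.ndarray  # in [0, 1]
    total_conc: float  # M
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        d = np.asarray(self.denaturant, dtype=float)
        y = np.asarray(self.fraction_monomer, dtype=float)
        if d.shape != y.shape or d.ndim != 1:
            raise ValueError("denaturant and fraction_monomer must match")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("fraction_monomer must lie in [0, 1]")
        if self.total_conc <= 0 or self.temperature <= 0:
            raise ValueError("total_conc and temperature must be positive")
        object.__setattr__(self, "denaturant", d)
        object.__setattr__(self, "fraction_monomer", y)


@dataclass(frozen=True)
class IsodesmicFit:
    """Recovered isodesmic parameters: the elongation free energy dG0
    (kJ/mol, negative for stable fibrils) and the denaturant m-value
    (kJ/(mol M))."""

    delta_g0: float
    m_value: float
    delta_g0_err: float
    m_value_err: float
    covariance: np.ndarray


def isodesmic_fraction(
    delta_g0: float,
    m_value: float,
    denaturant,
    total_conc: float,
    temperature: float = 298.15,
):
    """Free monomer fraction of the isodesmic linear-polymerisation model.

    With K = exp(-(dG0 + m [D]) / RT) per molar (1 M standard state) and
    x = K [M]_T:  y = (2x + 1 - sqrt(4x + 1)) / (2 x^2), evaluated in the
    algebraically equivalent, cancellation-free form
    y = 4 / (1 + sqrt(4x + 1))^2.  y -> 1 as x -> 0 and y is non-decreasing
    in dG0 + m [D].
    """
    if total_conc <= 0 or temperature <= 0:
        raise ValueError("total_conc and temperature must be positive")
    d = np.asarray(denaturant, dtype=float)
    rt = GAS_CONSTANT_KJ * temperature
    x = total_conc * np.exp(-(delta_g0 + m_value * d) / rt)
    y = 4.0 / (1.0 + np.sqrt(4.0 * x + 1.0)) ** 2
    return y if np.ndim(denaturant) else float(y)


def fit_isodesmic(curve: DepolymerisationCurve) -> IsodesmicFit:
    """Nonlinear least squares of the isodesmic depolymerisation curve.

    Initial values come from the mid-transition denaturant concentration
    (where y crosses 1/2, the isodesmic model has K [M]_T ~ 0.57) and a
    generic m-value; non-convergence (e.g. no transition in range) raises
    with a diagnostic.
    """
    d = curve.denaturant
    y = curve.fraction_monomer
    if len(d) < 4:
        raise ValueError("need at least 4 points to fit the isodesmic model")
    rt = GAS_CONSTANT_KJ * curve.temperature
    m0 = 2.0
    crossing = np.nonzero(np.diff(np.sign(y - 0.5)))[0]
    if len(crossing):
        d_half = 0.5 * (d[crossing[0]] + d[crossing[0] + 1])
    else:
        d_half = float(np.median(d))
    # at mid-transition K*[M]_T ~ 0.57  =>  dG0 + m*D_half = -RT ln(0.57/[M]_T)
    g0_0 = -rt * math.log(0.57 / curve.total_conc) - m0 * d_half

    def model(dd, g0, m):
        return isodesmic_fraction(g0, m, dd, curve.total_conc, curve.temperature)

    try:
        popt, pcov = curve_fit(
            model, d, y, p0=(g0_0, m0), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message forwarded
        raise RuntimeError(
            "isodesmic fit did not converge -- does the curve span the "
            f"depolymerisation transition? (initial guess dG0={g0_0:.1f}, m={m0})"
        ) from exc
    errs = np.sqrt(np.diag(pcov))
    return IsodesmicFit(
        delta_g0=float(popt[0]),
        m_value=float(popt[1]),
        delta_g0_err=float(errs[0]),
        m_value_err=float(errs[1]),
        covariance=pcov,
    )


# ---------------------------------------------------------------------------
# Buried hydrophobic surface area and the gamma-vs-area regression
# ---------------------------------------------------------------------------


def load_area_table(path: str | Path | None = None) -> dict:
    """Per-residue surface areas (Angstrom^2); defaults to the shipped
    maximal solvent-accessible surface area table."""
    path = _data_path("max_asa.tsv") if path is None else Path(path)
    table = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, val = line.split()
        table[aa] = float(val)
    return table


def hydrophobic_area(core_sequence: Sequence | str, area_table: dict | None = None) -> float:
    """Total hydrophobic surface area A_h = sum of a_i over hydrophobic
    residues of the fibril-core sequence."""
    seq = Sequence(core_sequence) if isinstance(core_sequence, str) else core_sequence
    table = load_area_table() if area_table is None else area_table
    total = 0.0
    for pos, aa in enumerate(seq.residues):
        if aa in HYDROPHOBIC_RESIDUES:
            if aa not in table:
                raise KeyError(
                    f"residue {aa!r} at position {pos} missing from the area table"
                )
            total += table[aa]
    return total


@dataclass(frozen=True)
class AreaRecord:
    """One system of the meta-analysis: its fibril-core sequence (or a
    precomputed area) and the fitted hydrophobic strength."""

    label: str
    gamma: float  # kJ/(mol K^2)
    a_h: float  # Angstrom^2

    def __post_init__(self) -> None:
        if self.a_h < 0:
            raise ValueError("a_h must be >= 0")


def fit_gamma_vs_area(records: TypingSequence[AreaRecord]):
    """Least-squares slope of gamma on A_h constrained through the origin.

    Returns ``(slope, slope_err, residuals)`` with the slope in
    kJ/(mol K^2 Angstrom^2).
    """
    if len(records) < 1:
        raise ValueError("need at least one record")
    a = np.array([r.a_h for r in records], dtype=float)
    g = np.array([r.gamma for r in records], dtype=float)
    if np.all(a == 0):
        raise ValueError("all A_h are zero; slope undefined")
    slope = float((a @ g) / (a @ a))
    resid = g - slope * a
    dof = max(len(records) - 1, 1)
    slope_err = float(np.sqrt((resid @ resid) / dof / (a @ a)))
    return slope, slope_err, resid


# ---------------------------------------------------------------------------
# Synthetic data generators (fixtures standing in for raw calorimetry)
# ---------------------------------------------------------------------------


def generate_synthetic_itc(
    gamma: float,
    e_int: float,
    temperatures=None,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    t0: float = T0_EXPERIMENTAL_K,
) -> ITCCurve:
    """ITC-style dH(T) data from the hydrophobic form, optionally with
    Gaussian noise; deterministic for a fixed seed, exact when sigma = 0."""
    t = (
        np.arange(278.15, 323.16, 5.0)
        if temperatures is None
        else np.asarray(temperatures, dtype=float)
    )
    dh = gamma * (t0 ** 2 - t ** 2) + e_int
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        dh = dh + rng.normal(0.0, noise_sigma, size=len(t))
    return ITCCurve(
        temperatures=t,
        delta_h=dh,
        sigma=np.full(len(t), noise_sigma) if noise_sigma > 0 else None,
    )


def generate_synthetic_depoly(
    delta_g0: float,
    m_value: float,
    total_conc: float = 10e-6,
    denaturant=None,
    temperature: float = 298.15,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> DepolymerisationCurve:
    """Depolymerisation curve from the isodesmic model, optionally with
    Gaussian noise on y (clipped to [0, 1])."""
    d = (
        np.linspace(0.0, 8.0, 25)
        if denaturant is None
        else np.asarray(denaturant, dtype=float)
    )
    y = isodesmic_fraction(delta_g0, m_value, d, total_conc, temperature)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        y = np.clip(y + rng.normal(0.0, noise_sigma, size=len(d)), 0.0, 1.0)
    return DepolymerisationCurve(
        denaturant=d,
        fraction_monomer=y,
        total_conc=total_conc,
        temperature=temperature,
    )
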