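"""Van 't Hoff dissolution thermodynamics from solubility–temperature data.

The modified Van 't Hoff treatment regresses ln x₁ on (1/T − 1/T_hm),
where T_hm is the harmonic mean of the experimental temperatures.  The
slope gives the apparent standard dissolution enthalpy, the intercept
the Gibbs energy at T_hm, and their difference over T_hm the entropy:

    Δ_sol H° = −R · slope
    Δ_sol G° = −R · T_hm · intercept
    Δ_sol S° = (Δ_sol H° − Δ_sol G°) / T_hm

The relative enthalpy/entropy contributions ζ_H and ζ_TS are computed
under the magnitude convention (absolute values of each term), which is
the convention consistent with a positive ζ_H alongside a negative
dissolution entropy.  Energies are carried in kJ·mol⁻¹ and the entropy
in kJ·K⁻¹·mol⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .constants import GAS_CONSTANT_R, WATER_MOLAR_MASS
from .core import (
    AlignmentError,
    DomainError,
    FitError,
    SolubilityTable,
    SoluteSpec,
    mole_fraction,
)


@dataclass(frozen=True)
class VantHoffFit:
    """Raw regression output of ln x₁ on (1/T − 1/T_hm)."""

    dsol_H: float  # kJ·mol⁻¹
    dsol_G: float  # kJ·mol⁻¹
    intercept: float
    slope: float
    r2: float
    t_hm: float
    n_points: int


@dataclass(frozen=True)
class DissolutionThermo:
    """Apparent dissolution thermodynamics of one solute/solvent system."""

    t_hm: float  # K
    dsol_H: float  # kJ·mol⁻¹
    dsol_G: float  # kJ·mol⁻¹
    dsol_S: float  # kJ·K⁻¹·mol⁻¹
    zeta_H: float
    zeta_TS: float
    fit_r2: float
    n_points: int


def harmonic_mean_temperature(temperatures: Iterable[float]) -> float:
    """Harmonic mean T_hm = n / Σ(1/T_j) of a set of temperatures (K)."""
    t = np.asarray(list(temperatures), dtype=float)
    if t.size == 0:
        raise DomainError("need at least one temperature")
    if np.any(t <= 0):
        raise DomainError("temperatures must be > 0 K")
    return float(t.size / np.sum(1.0 / t))


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = intercept + slope·x with R²."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise FitError("degenerate abscissa: all x identical")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (intercept + slope * x)
    sst = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    return intercept, slope, r2


def vant_hoff_fit(
    table: SolubilityTable,
    solute: SoluteSpec,
    water_molar_mass: float = WATER_MOLAR_MASS,
) -> VantHoffFit:
    """Fit the modified Van 't Hoff line to a solubility table."""
    if len(table) < 3:
        raise FitError("≥3 temperature points required")
    x1 = np.array(
        [mole_fraction(s, solute, water_molar_mass) for s in table.solubility]
    )
    if np.any(x1 <= 0):
        raise DomainError("mole fractions must be > 0 for the log transform")
    t_hm = harmonic_mean_temperature(table.temperature)
    x = 1.0 / table.temperature - 1.0 / t_hm
    intercept, slope, r2 = _ols_line(x, np.log(x1))
    dsol_H = -GAS_CONSTANT_R * slope / 1000.0
    dsol_G = -GAS_CONSTANT_R * t_hm * intercept / 1000.0
    return VantHoffFit(dsol_H, dsol_G, intercept, slope, r2, t_hm, len(table))


def dissolution_entropy(dsol_H: float, dsol_G: float, t_hm: float) -> float:
    """Δ_sol S° = (Δ_sol H° − Δ_sol G°)/T_hm, in kJ·K⁻¹·mol⁻¹."""
    if t_hm <= 0:
        raise DomainError("t_hm must be > 0")
    return (dsol_H - dsol_G) / t_hm


def enthalpy_entropy_contributions(
    dsol_H: float, dsol_S: float, t_hm: float
) -> tuple[float, float]:
    """Relative contributions ζ_H, ζ_TS under the magnitude convention.

    ζ_H = |ΔH| / (|ΔH| + |T_hm·ΔS|);  ζ_TS = 1 − ζ_H.
    """
    h = abs(dsol_H)
    ts = abs(t_hm * dsol_S)
    if h + ts == 0:
        raise DomainError("both enthalpy and entropy terms are zero")
    zeta_H = h / (h + ts)
    return zeta_H, 1.0 - zeta_H


def analyze_dissolution(
    table: SolubilityTable,
    solute: SoluteSpec,
    water_molar_mass: float = WATER_MOLAR_MASS,
) -> DissolutionThermo:
    """Full dissolution analysis: fit, entropy and ζ contributions."""
    fit = vant_hoff_fit(table, solute, water_molar_mass)
    dsol_S = dissolution_entropy(fit.dsol_H, fit.dsol_G, fit.t_hm)
    zeta_H, zeta_TS = enthalpy_entropy_contributions(fit.dsol_H, dsol_S, fit.t_hm)
    return DissolutionThermo(
        t_hm=fit.t_hm,
        dsol_H=fit.dsol_H,
        dsol_G=fit.dsol_G,
        dsol_S=dsol_S,
        zeta_H=zeta_H,
        zeta_TS=zeta_TS,
        fit_r2=fit.r2,
        n_points=fit.n_points,
    )


def solubility_ratio(
    numerator: SolubilityTable, denominator: SolubilityTable
) -> dict[float, float]:
    """Per-temperature solubility ratio of two tables on identical grids."""
    if not np.array_equal(numerator.temperature, denominator.temperature):
        raise AlignmentError("temperature grids differ")
    return {
        float(t): float(a / b)
        for t, a, b in zip(
            numerator.temperature, numerator.solubility, denominator.solubility
        )
    }
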