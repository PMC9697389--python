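"""Apparent molar volumes, Masson fits, expansibility and taste analysis.

From solution densities the apparent molar volume of the solute is

    V_φ = M/ρ − 1000·(ρ − ρ₀)/(m·ρ·ρ₀)      [cm³·mol⁻¹]

with M the solute molar mass (g·mol⁻¹), m the molality (mol·kg⁻¹) and
ρ, ρ₀ the solution and solvent densities (g·cm⁻³).  For a
non-electrolyte V_φ is linear in molality (Masson form for
non-electrolytes), V_φ = V_φ° + S_v·m; the intercept V_φ° is the
limiting apparent molar volume and the slope S_v reports solute–solute
interactions.

V_φ°(T) is then fitted with a quadratic in T, whose first derivative is
the limiting apparent molar expansibility E_φ° = a₁ + 2a₂T and whose
second derivative 2a₂ is the Hepler coefficient — negative values are
conventionally read as structure-breaking, positive as structure-making
(a criterion of limited force where the solute self-aggregates).

The apparent specific volume V_φ°/M maps to Birch taste-quality ranges:
salty [0.1, 0.3), sour [0.3, 0.5), sweet [0.5, 0.7), bitter [0.7, 0.9]
cm³·g⁻¹ (half-open, upper edge of bitter closed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AlignmentError,
    DensitySeries,
    DomainError,
    FitError,
    SoluteSpec,
    SolventReference,
    ValidationError,
)

#: Half-open Birch taste ranges for the apparent specific volume, cm³·g⁻¹.
TASTE_RANGES: tuple[tuple[float, float, str], ...] = (
    (0.1, 0.3, "salty"),
    (0.3, 0.5, "sour"),
    (0.5, 0.7, "sweet"),
    (0.7, 0.9, "bitter"),
)

#: Specific volumes within this distance of a range edge get a border flag.
BORDER_TOLERANCE = 0.015


@dataclass(frozen=True)
class MassonFit:
    """Per-temperature Masson line V_φ = V_φ° + S_v·m."""

    vphi0: float  # cm³·mol⁻¹
    sv: float  # cm³·kg·mol⁻²
    sigma: float  # residual std dev, cm³·mol⁻¹
    r2: float
    n_points: int


@dataclass(frozen=True)
class TasteClassification:
    specific_volume: float  # cm³·g⁻¹
    label: str
    border: bool


@dataclass(frozen=True)
class VolumetricResult:
    """All volumetric outputs on one temperature grid."""

    temperatures: tuple[float, ...]
    masson: tuple[MassonFit, ...]
    a0: float
    a1: float
    a2: float
    quadratic_r2: float
    ephi0_per_T: dict[float, float]
    hepler: float
    hepler_label: str
    taste: tuple[TasteClassification, ...]


def apparent_molar_volume(
    rho: float, rho0: float, m: float, solute: SoluteSpec
) -> float:
    """Apparent molar volume V_φ (cm³·mol⁻¹) from densities at molality m."""
    if m <= 0:
        raise DomainError("apparent molar volume undefined at m ≤ 0")
    if rho <= 0 or rho0 <= 0:
        raise DomainError("densities must be > 0")
    return solute.molar_mass / rho - 1000.0 * (rho - rho0) / (m * rho * rho0)


def masson_fit(vphi_vs_m: Sequence[tuple[float, float]]) -> MassonFit:
    """OLS fit of the Masson line to (m, V_φ) points at one temperature."""
    pts = np.asarray(vphi_vs_m, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise FitError("≥3 (m, V_φ) points required")
    m, v = pts[:, 0], pts[:, 1]
    if len(np.unique(m)) < 2:
        raise FitError("molalities are degenerate")
    sxx = np.sum((m - m.mean()) ** 2)
    sv = float(np.sum((m - m.mean()) * (v - v.mean())) / sxx)
    vphi0 = float(v.mean() - sv * m.mean())
    resid = v - (vphi0 + sv * m)
    ssr = float(np.sum(resid**2))
    sst = float(np.sum((v - v.mean()) ** 2))
    sigma = float(np.sqrt(ssr / (len(m) - 2))) if len(m) > 2 else 0.0
    r2 = 1.0 if sst == 0 else 1.0 - ssr / sst
    return MassonFit(vphi0, sv, sigma, r2, len(m))


def vphi0_temperature_fit(
    vphi0_per_T: Mapping[float, float]
) -> tuple[float, float, float, float]:
    """OLS quadratic V_φ°(T) = a₀ + a₁T + a₂T²; returns (a₀, a₁, a₂, R²)."""
    if len(vphi0_per_T) < 3:
        raise FitError("≥3 temperatures required for the quadratic fit")
    t = np.array(sorted(vphi0_per_T), dtype=float)
    v = np.array([vphi0_per_T[x] for x in t], dtype=float)
    a2, a1, a0 = np.polyfit(t, v, 2)
    fitted = a0 + a1 * t + a2 * t**2
    sst = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum((v - fitted) ** 2)) / sst
    return float(a0), float(a1), float(a2), r2


def expansibility(a1: float, a2: float, T: float) -> float:
    """Limiting apparent molar expansibility E_φ° = a₁ + 2a₂T."""
    return a1 + 2.0 * a2 * T


def hepler_coefficient(a2: float) -> tuple[float, str]:
    """Hepler coefficient 2a₂ with its structure label."""
    h = 2.0 * a2
    if h > 0:
        label = "structure-making"
    elif h < 0:
        label = "structure-breaking by Hepler criterion"
    else:
        label = "indeterminate"
    return h, label


def transfer_volume(vphi0_mixed: float, vphi0_water: float) -> float:
    """Limiting transfer volume Δ_tr V_φ° = V_φ°(mixed) − V_φ°(water)."""
    return vphi0_mixed - vphi0_water


def taste_classify(vphi0: float, solute: SoluteSpec) -> TasteClassification:
    """Birch taste label from the apparent specific volume V_φ°/M."""
    if vphi0 <= 0:
        raise DomainError("vphi0 must be > 0")
    sv = vphi0 / solute.molar_mass
    label = "unclassified"
    for lo, hi, name in TASTE_RANGES:
        closed_upper = name == "bitter"
        # tolerance absorbs float noise from the V_φ°/M division at the edge
        if lo <= sv < hi or (closed_upper and abs(sv - hi) < 1e-9):
            label = name
            break
    edges = sorted({e for lo, hi, _ in TASTE_RANGES for e in (lo, hi)})
    border = any(abs(sv - e) <= BORDER_TOLERANCE for e in edges)
    return TasteClassification(specific_volume=sv, label=label, border=border)


def analyze_volumetrics(
    density: DensitySeries, solvent: SolventReference, solute: SoluteSpec
) -> VolumetricResult:
    """Full volumetric chain: V_φ → Masson per T → quadratic T-fit → taste."""
    temps = density.temperatures
    fits = []
    for T in temps:
        m, rho = density.at_temperature(T)
        rho0 = solvent.rho0_at(T)
        nz = m > 0
        pts = [
            (mm, apparent_molar_volume(rr, rho0, mm, solute))
            for mm, rr in zip(m[nz], rho[nz])
        ]
        fits.append(masson_fit(pts))
    vphi0_per_T = {T: f.vphi0 for T, f in zip(temps, fits)}
    a0, a1, a2, q_r2 = vphi0_temperature_fit(vphi0_per_T)
    ephi0 = {T: expansibility(a1, a2, T) for T in temps}
    hepler, hepler_label = hepler_coefficient(a2)
    taste = tuple(taste_classify(f.vphi0, solute) for f in fits)
    return VolumetricResult(
        temperatures=tuple(float(t) for t in temps),
        masson=tuple(fits),
        a0=a0,
        a1=a1,
        a2=a2,
        quadratic_r2=q_r2,
        ephi0_per_T=ephi0,
        hepler=hepler,
        hepler_label=hepler_label,
        taste=taste,
    )
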