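"""Jones–Dole viscosity analysis and transition-state activation parameters.

For a non-electrolyte the Jones–Dole relation reduces to

    η/η₀ − 1 = B·c

with c the molar concentration (mol·dm⁻³); B (dm³·mol⁻¹) is fitted by
least squares through the origin.  B > 0 with dB/dT < 0 is the classic
signature of a structure-maker; B > 0 with dB/dT > 0 is termed an
atypical structure-maker; B < 0 a structure-breaker.

The transition-state treatment of viscous flow converts η₀, B and the
partial molar volumes into activation free energies per mole of solvent
(Δμ₁°≠) and of solute (Δμ₂°≠):

    Δμ₁°≠ = R·T·ln(η₀·V̄₁°/(h·N_A))
    Δμ₂°≠ = Δμ₁°≠ + (R·T/V̄₁°)·(1000·B + V̄₂° − V̄₁°)

with η₀ in Pa·s and V̄₁° in m³·mol⁻¹ inside the logarithm, and all
volumes in cm³·mol⁻¹ in the second relation (B converted dm³ → cm³).
The activation entropy is the negative temperature slope of Δμ₂°≠ and
the enthalpy follows from Δμ₂°≠ + T·ΔS₂°≠ evaluated on the fitted line
at a reference temperature (the harmonic mean by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .constants import AVOGADRO_NA, GAS_CONSTANT_R, PLANCK_H
from .core import (
    DensitySeries,
    DomainError,
    FitError,
    SoluteSpec,
    SolventReference,
    ViscositySeries,
    molarity_from_molality,
)


@dataclass(frozen=True)
class ViscometricResult:
    """Jones–Dole B per temperature and the structure classification."""

    B_per_T: dict[float, float]  # dm³·mol⁻¹
    dBdT: float  # dm³·mol⁻¹·K⁻¹
    classification: str
    fit_r2_per_T: dict[float, float]


@dataclass(frozen=True)
class ActivationResult:
    """Feakins transition-state parameters of viscous flow."""

    temperatures: tuple[float, ...]
    dmu1_per_T: dict[float, float]  # kJ·mol⁻¹
    dmu2_per_T: dict[float, float]  # kJ·mol⁻¹
    dS2: float  # J·mol⁻¹·K⁻¹
    dH2: float  # kJ·mol⁻¹
    t_ref: float  # K


def jones_dole_fit(
    viscosity: ViscositySeries,
    density: DensitySeries,
    solvent: SolventReference,
    solute: SoluteSpec,
    T: float,
) -> tuple[float, float]:
    """Fit η/η₀ − 1 = B·c through the origin at one temperature.

    Returns (B in dm³·mol⁻¹, R² about the origin-constrained line).
    """
    eta0 = solvent.eta0_at(T)
    m, eta = viscosity.at_temperature(T)
    nz = m > 0
    m, eta = m[nz], eta[nz]
    if len(m) < 3:
        raise FitError(f"≥3 nonzero molalities required at {T} K")
    c = np.array(
        [molarity_from_molality(mm, density.lookup(mm, T), solute) for mm in m]
    )
    y = eta / eta0 - 1.0
    B = float(np.sum(c * y) / np.sum(c * c))
    resid = y - B * c
    sst = float(np.sum(y**2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    return B, r2


def structure_classify(B_per_T: Mapping[float, float]) -> tuple[str, float]:
    """Classify the solute from the signs of B and dB/dT.

    Returns (label, dB/dT) where dB/dT is the OLS slope of B against T.
    """
    if len(B_per_T) < 2:
        raise FitError("≥2 temperatures required to estimate dB/dT")
    t = np.array(sorted(B_per_T), dtype=float)
    b = np.array([B_per_T[x] for x in t], dtype=float)
    slope = float(np.polyfit(t, b, 1)[0])
    if np.all(b > 0):
        label = "structure-maker" if slope < 0 else "atypical structure-maker"
    elif np.all(b < 0):
        label = "structure-breaker"
    else:
        label = "indeterminate"
    return label, slope


def activation_mu1(eta0: float, v1bar: float, T: float) -> float:
    """Δμ₁°≠ (kJ·mol⁻¹) from solvent viscosity (mPa·s) and V̄₁° (cm³·mol⁻¹)."""
    if eta0 <= 0 or v1bar <= 0 or T <= 0:
        raise DomainError("eta0, v1bar and T must be > 0")
    arg = (eta0 * 1e-3) * (v1bar * 1e-6) / (PLANCK_H * AVOGADRO_NA)
    if arg <= 0:
        raise DomainError("non-positive argument to the logarithm")
    return GAS_CONSTANT_R * T * float(np.log(arg)) / 1000.0


def activation_mu2(
    dmu1: float, B: float, v1bar: float, v2bar: float, T: float
) -> float:
    """Δμ₂°≠ (kJ·mol⁻¹) per mole of solute.

    B in dm³·mol⁻¹ is converted to cm³·mol⁻¹ and combined with the
    volumes as (1000·B + V̄₂° − V̄₁°).
    """
    if v1bar <= 0:
        raise DomainError("v1bar must be > 0")
    volume_term = 1000.0 * B + v2bar - v1bar  # cm³·mol⁻¹
    return dmu1 + GAS_CONSTANT_R * T / v1bar * volume_term / 1000.0


def activation_entropy_enthalpy(
    dmu2_per_T: Mapping[float, float], t_ref: float
) -> tuple[float, float]:
    """ΔS₂°≠ (J·mol⁻¹·K⁻¹) and ΔH₂°≠ (kJ·mol⁻¹) from the Δμ₂°≠(T) line.

    ΔS₂°≠ = −slope of the OLS line (converted kJ → J); ΔH₂°≠ is the
    fitted-line value at ``t_ref`` plus T_ref·ΔS₂°≠.
    """
    if len(dmu2_per_T) < 3:
        raise FitError("≥3 temperatures required")
    t = np.array(sorted(dmu2_per_T), dtype=float)
    mu = np.array([dmu2_per_T[x] for x in t], dtype=float)
    slope, intercept = np.polyfit(t, mu, 1)
    dS2 = -1000.0 * float(slope)
    dmu2_ref = float(intercept + slope * t_ref)
    dH2 = dmu2_ref + t_ref * dS2 / 1000.0
    return dS2, dH2


def analyze_viscometrics(
    viscosity: ViscositySeries,
    density: DensitySeries,
    solvent: SolventReference,
    solute: SoluteSpec,
) -> ViscometricResult:
    """Jones–Dole B at every temperature plus the structure classification."""
    B_per_T: dict[float, float] = {}
    r2_per_T: dict[float, float] = {}
    for T in viscosity.temperatures:
        B, r2 = jones_dole_fit(viscosity, density, solvent, solute, T)
        B_per_T[float(T)] = B
        r2_per_T[float(T)] = r2
    label, slope = structure_classify(B_per_T)
    return ViscometricResult(
        B_per_T=B_per_T, dBdT=slope, classification=label, fit_r2_per_T=r2_per_T
    )


def analyze_activation(
    B_per_T: Mapping[float, float],
    v2bar_per_T: Mapping[float, float],
    solvent: SolventReference,
    t_ref: float | None = None,
) -> ActivationResult:
    """Activation chain Δμ₁°≠ → Δμ₂°≠ → (ΔS₂°≠, ΔH₂°≠) over a T grid."""
    temps = tuple(sorted(B_per_T))
    if set(temps) - set(v2bar_per_T):
        raise DomainError("v2bar grid does not cover the B grid")
    dmu1 = {
        T: activation_mu1(solvent.eta0_at(T), solvent.v1bar_at(T), T) for T in temps
    }
    dmu2 = {
        T: activation_mu2(
            dmu1[T], B_per_T[T], solvent.v1bar_at(T), v2bar_per_T[T], T
        )
        for T in temps
    }
    if t_ref is None:
        t_ref = float(len(temps) / np.sum(1.0 / np.asarray(temps)))
    dS2, dH2 = activation_entropy_enthalpy(dmu2, t_ref)
    return ActivationResult(
        temperatures=temps,
        dmu1_per_T=dmu1,
        dmu2_per_T=dmu2,
        dS2=dS2,
        dH2=dH2,
        t_ref=t_ref,
    )
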