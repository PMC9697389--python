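"""Synthetic measurement tables with the structure the analysis assumes.

Each generator is the exact inversion of the corresponding analysis
relation, plus homoscedastic Gaussian instrument noise:

* densities invert the apparent-molar-volume relation for a Masson-law
  V_φ(m, T) = V_φ°(T) + S_v(T)·m;
* viscosities invert the Jones–Dole relation η = η₀·(1 + B·c) with c
  computed from the generated densities;
* solubilities invert the Van 't Hoff line
  ln x₁ = −ΔG/(R·T_hm) − (ΔH/R)·(1/T − 1/T_hm).

At zero noise the downstream fits therefore recover the ground truth to
machine precision — the property the recovery tests assert.  Noise
defaults reflect vibrating-tube densimeter (5·10⁻⁶ g·cm⁻³) and
rolling-ball viscometer (5·10⁻⁴ mPa·s) precision, and 1% relative
scatter on solubility (0.01 on ln x₁).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import GAS_CONSTANT_R
from .core import (
    AlignmentError,
    DensitySeries,
    DomainError,
    SolubilityTable,
    SoluteSpec,
    SolventReference,
    ValidationError,
    ViscositySeries,
)
from .dissolution import harmonic_mean_temperature

#: Default molality grid, mol·kg⁻¹ (8 points over the measured range).
DEFAULT_MOLALITIES: tuple[float, ...] = tuple(
    float(x) for x in np.linspace(0.01, 0.105, 8)
)

DEFAULT_NOISE_RHO = 5e-6  # g·cm⁻³
DEFAULT_NOISE_ETA = 5e-4  # mPa·s
DEFAULT_NOISE_LNX = 0.01  # on ln x₁


@dataclass(frozen=True)
class GroundTruth:
    """Hidden parameters of the generators; the recovery-test oracle."""

    vphi0_per_T: Mapping[float, float]  # cm³·mol⁻¹
    sv_per_T: Mapping[float, float]  # cm³·kg·mol⁻²
    B_per_T: Mapping[float, float]  # dm³·mol⁻¹
    dsol_H: float  # kJ·mol⁻¹
    dsol_G: float  # kJ·mol⁻¹
    noise_rho: float = DEFAULT_NOISE_RHO
    noise_eta: float = DEFAULT_NOISE_ETA
    noise_lnx: float = DEFAULT_NOISE_LNX
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.noise_rho, self.noise_eta, self.noise_lnx) < 0:
            raise ValidationError("noise terms must be ≥ 0")
        grids = {
            tuple(sorted(m)) for m in (self.vphi0_per_T, self.sv_per_T, self.B_per_T)
        }
        if len(grids) != 1:
            raise ValidationError("ground-truth temperature grids differ")

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(sorted(self.vphi0_per_T))


def _rng(truth: GroundTruth, stream: str) -> np.random.Generator:
    # one independent, reproducible stream per generated table;
    # crc32 (not hash()) so the streams survive interpreter restarts
    return np.random.default_rng([truth.seed, zlib.crc32(stream.encode()) % (2**31)])


def generate_density(
    truth: GroundTruth,
    solvent: SolventReference,
    solute: SoluteSpec,
    molalities: Sequence[float] = DEFAULT_MOLALITIES,
) -> DensitySeries:
    """Densities whose apparent molar volumes follow the Masson line."""
    if any(m <= 0 for m in molalities):
        raise DomainError("molalities must be > 0 (V_φ undefined at m = 0)")
    for T in truth.temperatures:
        if T not in solvent.rho0:
            raise AlignmentError(f"solvent grid lacks {T} K")
    rng = _rng(truth, "density")
    M = solute.molar_mass
    rows_m, rows_t, rows_rho = [], [], []
    for T in truth.temperatures:
        rho0 = solvent.rho0_at(T)
        for m in molalities:
            vphi = truth.vphi0_per_T[T] + truth.sv_per_T[T] * m
            rho = rho0 * (M * m + 1000.0) / (vphi * m * rho0 + 1000.0)
            rows_m.append(m)
            rows_t.append(T)
            rows_rho.append(rho + rng.normal(0.0, truth.noise_rho) if truth.noise_rho else rho)
    return DensitySeries(
        molality=np.array(rows_m), temperature=np.array(rows_t), density=np.array(rows_rho)
    )


def generate_viscosity(
    truth: GroundTruth,
    solvent: SolventReference,
    solute: SoluteSpec,
    molalities: Sequence[float],
    density: DensitySeries,
) -> ViscositySeries:
    """Viscosities following η = η₀·(1 + B·c), c from the density series."""
    from .core import molarity_from_molality

    rng = _rng(truth, "viscosity")
    rows_m, rows_t, rows_eta = [], [], []
    for T in truth.temperatures:
        eta0 = solvent.eta0_at(T)
        for m in molalities:
            rho = density.lookup(m, T)
            c = molarity_from_molality(m, rho, solute)
            eta = eta0 * (1.0 + truth.B_per_T[T] * c)
            rows_m.append(m)
            rows_t.append(T)
            rows_eta.append(eta + rng.normal(0.0, truth.noise_eta) if truth.noise_eta else eta)
    return ViscositySeries(
        molality=np.array(rows_m), temperature=np.array(rows_t), viscosity=np.array(rows_eta)
    )


def generate_solubility(
    truth: GroundTruth,
    solute: SoluteSpec,
    temperatures: Sequence[float],
    water_molar_mass: float = 18.015,
) -> SolubilityTable:
    """Solubility table on the Van 't Hoff line defined by (ΔH, ΔG)."""
    if len(temperatures) < 3:
        raise DomainError("≥3 temperatures required")
    t = np.asarray(temperatures, dtype=float)
    t_hm = harmonic_mean_temperature(t)
    R = GAS_CONSTANT_R
    lnx = (
        -truth.dsol_G * 1000.0 / (R * t_hm)
        - truth.dsol_H * 1000.0 / R * (1.0 / t - 1.0 / t_hm)
    )
    if truth.noise_lnx:
        lnx = lnx + _rng(truth, "solubility").normal(0.0, truth.noise_lnx, size=len(t))
    x1 = np.exp(lnx)
    if np.any(x1 >= 1.0):
        raise DomainError("parameters yield mole fraction ≥ 1")
    n_water = 1000.0 / water_molar_mass
    n_solute = x1 * n_water / (1.0 - x1)
    return SolubilityTable(temperature=t, solubility=n_solute * solute.molar_mass)
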