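"""Domain types and elementary conversions shared by every stage.

Measurement tables are thin, validated wrappers around numpy arrays.
Validation happens at construction: an instance that exists satisfies
its invariants, so downstream code never re-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .constants import WATER_MOLAR_MASS


class CaffsolError(Exception):
    """Base class for all package errors."""


class ValidationError(CaffsolError):
    """A table or type invariant is violated."""


class SchemaError(CaffsolError):
    """Input file header does not match the expected schema."""


class TableParseError(CaffsolError):
    """A cell could not be parsed as a number."""


class DomainError(CaffsolError):
    """An argument is outside the mathematical domain of an operation."""


class AlignmentError(CaffsolError):
    """Two inputs that must share a temperature grid do not."""


class FitError(CaffsolError):
    """Not enough (or degenerate) data for a regression."""


@dataclass(frozen=True)
class SoluteSpec:
    """A solute identified by name and molar mass (g·mol⁻¹)."""

    name: str
    molar_mass: float

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValidationError(f"molar_mass must be > 0, got {self.molar_mass}")


CAFFEINE = SoluteSpec("caffeine", 194.19)


def _as_temperature_map(values: Mapping[float, float]) -> dict[float, float]:
    return {float(t): float(v) for t, v in values.items()}


@dataclass(frozen=True)
class SolventReference:
    """Pure-solvent baseline: ρ₀(T), η₀(T) and V̄₁°(T) on one T grid.

    ``cosolute_molality`` is 0 for pure water and the fixed background
    molality (mol·kg⁻¹) for a mixed solvent such as aqueous sodium
    salicylate.  ``v1bar`` is the partial molar volume of water at
    infinite dilution (cm³·mol⁻¹); it is an input, not derived from ρ₀.
    """

    description: str
    rho0: Mapping[float, float]  # T (K) -> g·cm⁻³
    eta0: Mapping[float, float]  # T (K) -> mPa·s
    v1bar: Mapping[float, float]  # T (K) -> cm³·mol⁻¹
    cosolute_molality: float = 0.0
    water_molar_mass: float = WATER_MOLAR_MASS

    def __post_init__(self) -> None:
        object.__setattr__(self, "rho0", _as_temperature_map(self.rho0))
        object.__setattr__(self, "eta0", _as_temperature_map(self.eta0))
        object.__setattr__(self, "v1bar", _as_temperature_map(self.v1bar))
        grids = {tuple(sorted(m)) for m in (self.rho0, self.eta0, self.v1bar)}
        if len(grids) != 1:
            raise ValidationError("rho0/eta0/v1bar temperature grids differ")
        for name, m in (("rho0", self.rho0), ("eta0", self.eta0), ("v1bar", self.v1bar)):
            if any(v <= 0 for v in m.values()):
                raise ValidationError(f"{name} values must all be > 0")

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(sorted(self.rho0))

    def _lookup(self, table: Mapping[float, float], T: float, name: str) -> float:
        try:
            return table[float(T)]
        except KeyError:
            raise AlignmentError(
                f"temperature {T} K not on the solvent {name} grid {self.temperatures}"
            ) from None

    def rho0_at(self, T: float) -> float:
        return self._lookup(self.rho0, T, "rho0")

    def eta0_at(self, T: float) -> float:
        return self._lookup(self.eta0, T, "eta0")

    def v1bar_at(self, T: float) -> float:
        return self._lookup(self.v1bar, T, "v1bar")


@dataclass(frozen=True)
class SolubilityTable:
    """Solubility (g per 1000 g of solvent water) vs temperature (K)."""

    temperature: np.ndarray
    solubility: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.solubility, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValidationError("temperature and solubility must be 1-D and equal length")
        order = np.argsort(t)
        t, s = t[order], s[order]
        if len(np.unique(t)) < 3:
            raise ValidationError("≥3 distinct temperatures required")
        if len(np.unique(t)) != len(t):
            raise ValidationError("temperatures must be distinct")
        if np.any(s <= 0):
            raise ValidationError("solubility values must be > 0")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "solubility", s)

    def __len__(self) -> int:
        return len(self.temperature)


def _validate_series(molality, temperature, value, value_name: str):
    m = np.asarray(molality, dtype=float)
    t = np.asarray(temperature, dtype=float)
    v = np.asarray(value, dtype=float)
    if not (m.shape == t.shape == v.shape) or m.ndim != 1:
        raise ValidationError("series columns must be 1-D and equal length")
    if np.any(m < 0):
        bad = int(np.flatnonzero(m < 0)[0])
        raise ValidationError(f"negative molality at row {bad}")
    if np.any(v <= 0):
        bad = int(np.flatnonzero(v <= 0)[0])
        raise ValidationError(f"non-positive {value_name} at row {bad}")
    order = np.lexsort((m, t))
    m, t, v = m[order], t[order], v[order]
    for T in np.unique(t):
        if np.count_nonzero(m[t == T] > 0) < 3:
            raise ValidationError(
                f"temperature {T} K has fewer than 3 nonzero molalities"
            )
    return m, t, v


@dataclass(frozen=True)
class DensitySeries:
    """(molality, temperature, density) triples, sorted by (T, m)."""

    molality: np.ndarray
    temperature: np.ndarray
    density: np.ndarray  # g·cm⁻³

    def __post_init__(self) -> None:
        m, t, v = _validate_series(self.molality, self.temperature, self.density, "density")
        object.__setattr__(self, "molality", m)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "density", v)

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(np.unique(self.temperature))

    def at_temperature(self, T: float) -> tuple[np.ndarray, np.ndarray]:
        mask = self.temperature == float(T)
        if not mask.any():
            raise AlignmentError(f"no density rows at {T} K")
        return self.molality[mask], self.density[mask]

    def lookup(self, m: float, T: float) -> float:
        mask = (self.temperature == float(T)) & (self.molality == float(m))
        if not mask.any():
            raise AlignmentError(f"no density row at (m={m}, T={T})")
        return float(self.density[mask][0])

    def __len__(self) -> int:
        return len(self.molality)


@dataclass(frozen=True)
class ViscositySeries:
    """(molality, temperature, viscosity) triples, sorted by (T, m)."""

    molality: np.ndarray
    temperature: np.ndarray
    viscosity: np.ndarray  # mPa·s

    def __post_init__(self) -> None:
        m, t, v = _validate_series(
            self.molality, self.temperature, self.viscosity, "viscosity"
        )
        object.__setattr__(self, "molality", m)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "viscosity", v)

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(np.unique(self.temperature))

    def at_temperature(self, T: float) -> tuple[np.ndarray, np.ndarray]:
        mask = self.temperature == float(T)
        if not mask.any():
            raise AlignmentError(f"no viscosity rows at {T} K")
        return self.molality[mask], self.viscosity[mask]

    def __len__(self) -> int:
        return len(self.molality)


def mole_fraction(
    solubility_g_per_kg: float,
    solute: SoluteSpec,
    water_molar_mass: float = WATER_MOLAR_MASS,
) -> float:
    """Mole fraction of solute in water, from g solute per 1000 g water.

    x₁ = n₂ / (n₂ + n₁) with n₁ = 1000 / M_water.  The cosolute (if any)
    is excluded from the denominator: caffeine + water only.
    """
    if solubility_g_per_kg < 0:
        raise DomainError(f"solubility must be ≥ 0, got {solubility_g_per_kg}")
    n_solute = solubility_g_per_kg / solute.molar_mass
    n_water = 1000.0 / water_molar_mass
    return n_solute / (n_solute + n_water)


def molarity_from_molality(m: float, rho: float, solute: SoluteSpec) -> float:
    """Convert molality (mol·kg⁻¹) to molarity (mol·dm⁻³).

    c = m·ρ / (1 + m·M/1000), exact for a binary solution with solution
    density ρ in g·cm⁻³.
    """
    if m < 0:
        raise DomainError(f"molality must be ≥ 0, got {m}")
    if rho <= 0:
        raise DomainError(f"density must be > 0, got {rho}")
    return m * rho / (1.0 + m * solute.molar_mass / 1000.0)
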