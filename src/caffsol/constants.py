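"""Physical constants and unit conventions.

The pipeline uses one fixed unit system throughout: temperature in K,
molality in mol·kg⁻¹, density in g·cm⁻³, viscosity in mPa·s, molar
volumes in cm³·mol⁻¹, Jones–Dole B in dm³·mol⁻¹ and energies in
kJ·mol⁻¹.  Conversions to SI happen once, inside the operation that
needs them.
"""

from __future__ import annotations

from dataclasses import dataclass

GAS_CONSTANT_R = 8.314
"""Universal gas constant, J·K⁻¹·mol⁻¹."""

PLANCK_H = 6.62607015e-34
"""Planck constant, J·s."""

AVOGADRO_NA = 6.02214076e23
"""Avogadro constant, mol⁻¹."""

WATER_MOLAR_MASS = 18.015
"""Default molar mass of water, g·mol⁻¹ (overridable in config)."""

CAFFEINE_MOLAR_MASS = 194.19
"""Molar mass of anhydrous caffeine, g·mol⁻¹."""


@dataclass(frozen=True)
class Constants:
    """Read-only bundle of the physical constants the pipeline uses."""

    R: float = GAS_CONSTANT_R
    planck_h: float = PLANCK_H
    avogadro_NA: float = AVOGADRO_NA


CONSTANTS = Constants()
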