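"""Hydration numbers by the volumetric and viscometric routes.

Volumetric route: the electrostriction partial molar volume V_φ°(elect)
divided by the molar volume difference between electrostricted and bulk
water, h_n = V_φ°(elect)/(Ve° − Vb°).  Both quantities are negative for
a hydrated solute, giving a positive count of bound waters.

Viscometric route (Einstein-relation form): the hydrodynamic volume
implied by B over the shape factor (2.5 for spheres), minus the solute's
own limiting volume, expressed in moles of water:

    h_n = (1000·B/shape − V_φ°) / V̄₁°

The shape factor is configurable; conventions differ between sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import warnings

from .core import AlignmentError, DomainError, ValidationError
from .viscometrics import ViscometricResult
from .volumetrics import VolumetricResult

#: Default (Ve° − Vb°)(T) table, cm³·mol⁻¹ — literature convention,
#: configurable; not a measured property of this dataset.
DEFAULT_VE_MINUS_VB: dict[float, float] = {
    293.15: -3.6,
    298.15: -3.3,
    303.15: -3.0,
    308.15: -2.8,
    313.15: -2.6,
}


@dataclass(frozen=True)
class ElectrostrictionConfig:
    """How the volumetric route obtains its two inputs.

    ``elect_volume_mode`` is "direct-input" (the caller supplies
    V_φ°(elect) per temperature) or "intrinsic-subtraction"
    (V_φ°(elect) = V_φ° − V_intrinsic with a user-supplied intrinsic
    volume).
    """

    ve_minus_vb: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_VE_MINUS_VB)
    )
    elect_volume_mode: str = "direct-input"
    intrinsic_volume: float = 0.0
    vphi_elect_per_T: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ve_minus_vb:
            raise ValidationError("ve_minus_vb table is empty")
        if any(v >= 0 for v in self.ve_minus_vb.values()):
            raise ValidationError("(Ve° − Vb°) must be negative at every T")
        if self.elect_volume_mode not in ("direct-input", "intrinsic-subtraction"):
            raise ValidationError(
                f"unknown elect_volume_mode {self.elect_volume_mode!r}"
            )

    def ve_minus_vb_at(self, T: float) -> float:
        try:
            return self.ve_minus_vb[float(T)]
        except KeyError:
            raise AlignmentError(f"{T} K not on the (Ve°−Vb°) grid") from None


@dataclass(frozen=True)
class HydrationRow:
    temperature: float
    hn_volumetric: float | None
    hn_viscometric: float
    inputs_used: dict


@dataclass(frozen=True)
class HydrationResult:
    rows: tuple[HydrationRow, ...]
    viscometric_monotone_decreasing: bool


def hydration_volumetric(
    vphi_elect: float, config: ElectrostrictionConfig, T: float
) -> float:
    """h_n = V_φ°(elect)/(Ve° − Vb°) at temperature T."""
    hn = vphi_elect / config.ve_minus_vb_at(T)
    if hn < 0:
        warnings.warn(
            f"negative hydration number at {T} K: vphi_elect and (Ve°−Vb°) "
            "have mixed signs",
            stacklevel=2,
        )
    return hn


def hydration_viscometric(
    B: float, vphi0: float, v1bar: float, shape_factor: float = 2.5
) -> float:
    """Einstein-form viscometric hydration number.

    B in dm³·mol⁻¹, volumes in cm³·mol⁻¹.
    """
    if v1bar <= 0:
        raise DomainError("v1bar must be > 0")
    if shape_factor <= 0:
        raise DomainError("shape_factor must be > 0")
    return (1000.0 * B / shape_factor - vphi0) / v1bar


def hydration_table(
    volumetric: VolumetricResult,
    viscometric: ViscometricResult,
    config: ElectrostrictionConfig,
    v1bar_per_T: Mapping[float, float],
    shape_factor: float = 2.5,
) -> HydrationResult:
    """Evaluate both hydration routes on the shared temperature grid.

    The volumetric route is evaluated only where the config can supply
    V_φ°(elect); rows without it carry ``None`` there.
    """
    temps = volumetric.temperatures
    if set(temps) != set(viscometric.B_per_T):
        raise AlignmentError("volumetric and viscometric temperature grids differ")
    if set(temps) - set(v1bar_per_T):
        raise AlignmentError("v1bar grid does not cover the analysis grid")
    rows = []
    for T, fit in zip(temps, volumetric.masson):
        B = viscometric.B_per_T[T]
        v1 = v1bar_per_T[T]
        hn_visc = hydration_viscometric(B, fit.vphi0, v1, shape_factor)
        vphi_elect: float | None
        if config.elect_volume_mode == "intrinsic-subtraction":
            vphi_elect = fit.vphi0 - config.intrinsic_volume
        else:
            vphi_elect = config.vphi_elect_per_T.get(T)
        hn_vol = (
            hydration_volumetric(vphi_elect, config, T)
            if vphi_elect is not None
            else None
        )
        rows.append(
            HydrationRow(
                temperature=T,
                hn_volumetric=hn_vol,
                hn_viscometric=hn_visc,
                inputs_used={
                    "B_dm3_mol": B,
                    "vphi0_cm3_mol": fit.vphi0,
                    "v1bar_cm3_mol": v1,
                    "shape_factor": shape_factor,
                    "vphi_elect_cm3_mol": vphi_elect,
                    "ve_minus_vb_cm3_mol": config.ve_minus_vb.get(T),
                },
            )
        )
    hn = [r.hn_viscometric for r in rows]
    decreasing = all(a > b for a, b in zip(hn, hn[1:]))
    return HydrationResult(rows=tuple(rows), viscometric_monotone_decreasing=decreasing)
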