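"""Packaged reference datasets for caffeine in water and in 0.1 mol·kg⁻¹
aqueous sodium salicylate (SS).

The solubility tables, Masson parameters, Jones–Dole B-coefficients and
activation inputs are the published reference values for this system.
Two files are not measured data and say so in their names:

* ``solvent_ss_synthetic.csv`` — η₀(T) of the SS solvent back-solved
  from the published Δμ₁°≠ row (exact inversion of the activation
  relation); ρ₀(T) synthetic (water density plus an assumed SS apparent
  molar volume of 94 cm³·mol⁻¹).  Used only by the synthetic generator.
* ``water_vphi0_backsolved.csv`` — water-system V_φ°(T) back-solved
  from the SS Masson intercepts minus the published transfer volumes;
  a consistency fixture, not an independent measurement.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .core import SolubilityTable, SolventReference
from .io import read_table


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV."""
    return Path(resources.files("caffsol") / "fixtures" / name)


def solubility_table(system: str = "water") -> SolubilityTable:
    """Measured caffeine solubility vs T, ``system`` in {water, ss}."""
    return read_table(fixture_path(f"table1_solubility_{system}.csv"), "solubility")


def dissolution_reference() -> pd.DataFrame:
    """Published apparent ΔG°/ΔH° of dissolution, indexed by system."""
    return pd.read_csv(fixture_path("table2_dissolution_reference.csv")).set_index(
        "system"
    )


def masson_parameters() -> pd.DataFrame:
    """Published Masson fit parameters (V_φ°, S_v, σ, R²) per temperature."""
    return pd.read_csv(fixture_path("table3_masson.csv"))


def transfer_reference() -> pd.DataFrame:
    """Published transfer volumes and apparent specific volumes per T."""
    return pd.read_csv(fixture_path("table5_transfer.csv"))


def jones_dole_b() -> pd.DataFrame:
    """Published Jones–Dole B-coefficients (SS and water columns) per T."""
    return pd.read_csv(fixture_path("table6_jones_dole.csv"))


def activation_inputs() -> pd.DataFrame:
    """Published V̄₁°, V̄₂°, Δμ₁°≠, Δμ₂°≠ rows per temperature."""
    return pd.read_csv(fixture_path("table7_activation.csv"))


def ss_solvent_reference() -> SolventReference:
    """SS-solvent baseline (η₀ back-solved, ρ₀ synthetic — see module doc)."""
    ref = read_table(fixture_path("solvent_ss_synthetic.csv"), "solvent")
    return SolventReference(
        description="0.1 mol/kg aqueous sodium salicylate (eta0 back-solved, rho0 synthetic)",
        rho0=ref.rho0,
        eta0=ref.eta0,
        v1bar=ref.v1bar,
        cosolute_molality=0.1,
    )


def water_solvent_reference() -> SolventReference:
    """Pure-water baseline (standard reference densities/viscosities)."""
    ref = read_table(fixture_path("solvent_water.csv"), "solvent")
    return SolventReference(
        description="pure water",
        rho0=ref.rho0,
        eta0=ref.eta0,
        v1bar=ref.v1bar,
        cosolute_molality=0.0,
    )


def default_ground_truth(seed: int = 0) -> "GroundTruth":
    """Ground truth for the synthetic generators, at the study conditions.

    Masson parameters and B-coefficients come from the published SS-system
    fits; the Van 't Hoff pair is the published SS dissolution reference.
    """
    from .synthetic import GroundTruth

    masson = masson_parameters()
    b = jones_dole_b()
    ref = dissolution_reference().loc["ss"]
    return GroundTruth(
        vphi0_per_T=dict(zip(masson["temperature_K"], masson["vphi0_cm3_mol"])),
        sv_per_T=dict(zip(masson["temperature_K"], masson["sv_cm3_kg_mol2"])),
        B_per_T=dict(zip(b["temperature_K"], b["B_ss_dm3_mol"])),
        dsol_H=float(ref["dsol_H_kJ_mol"]),
        dsol_G=float(ref["dsol_G_kJ_mol"]),
        seed=seed,
    )


def water_vphi0() -> dict[float, float]:
    """Back-solved water-system V_φ°(T) consistency fixture."""
    df = pd.read_csv(fixture_path("water_vphi0_backsolved.csv"))
    return dict(zip(df["temperature_K"], df["vphi0_cm3_mol"]))
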