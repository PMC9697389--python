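#!/usr/bin/env python
"""Volumetric analysis: Masson fits, expansibility, Hepler, transfer, taste.

Runs the full density→V_φ→Masson chain on the synthetic density series
from step 01 (recovering the reference parameters), then evaluates the
temperature fit, expansibility, Hepler coefficient, transfer volumes
against the water system and the Birch taste classification on the
reference V_φ° values.
"""

import dataclasses
from pathlib import Path

from caffsol import CAFFEINE, analyze_volumetrics, transfer_volume
from caffsol.fixtures import ss_solvent_reference, water_vphi0
from caffsol.io import read_table, write_results

out = Path("results")
density = read_table(out / "synthetic/density.csv", "density")
solvent = ss_solvent_reference()

result = analyze_volumetrics(density, solvent, CAFFEINE)
w_vphi0 = water_vphi0()
transfer = {T: transfer_volume(f.vphi0, w_vphi0[T])
            for T, f in zip(result.temperatures, result.masson)}

write_results({
    "volumetrics": dataclasses.asdict(result),
    "transfer_volume_vs_water": transfer,
}, out / "volumetrics.json")

print("T/K      Vphi0    Sv      sigma   R2      E_phi0   taste")
for T, f, taste in zip(result.temperatures, result.masson, result.taste):
    print(f"{T:7.2f} {f.vphi0:8.2f} {f.sv:7.2f} {f.sigma:6.3f} {f.r2:7.4f} "
          f"{result.ephi0_per_T[T]:8.4f}  {taste.label}"
          + (" (border)" if taste.border else ""))
print(f"Hepler coefficient 2a2 = {result.hepler:+.4f} cm3/mol/K2 -> {result.hepler_label}")
print("transfer volumes vs water:",
      {T: round(v, 2) for T, v in transfer.items()})
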