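#!/usr/bin/env python
"""Hydration numbers of caffeine in the SS solution, both routes.

Combines the volumetric (step 03) and viscometric (step 04) analyses of
the synthetic series into per-temperature hydration numbers.  The
viscometric route uses the Einstein-form default (shape factor 2.5);
the volumetric route runs in intrinsic-subtraction mode with an assumed
intrinsic molar volume, against the configurable literature
(Ve°−Vb°)(T) table.
"""

import dataclasses
from pathlib import Path

from caffsol import (
    CAFFEINE,
    ElectrostrictionConfig,
    analyze_viscometrics,
    analyze_volumetrics,
    hydration_table,
)
from caffsol.fixtures import ss_solvent_reference
from caffsol.io import read_table, write_results

out = Path("results")
density = read_table(out / "synthetic/density.csv", "density")
viscosity = read_table(out / "synthetic/viscosity.csv", "viscosity")
solvent = ss_solvent_reference()

vol = analyze_volumetrics(density, solvent, CAFFEINE)
visc = analyze_viscometrics(viscosity, density, solvent, CAFFEINE)
cfg = ElectrostrictionConfig(
    elect_volume_mode="intrinsic-subtraction", intrinsic_volume=144.0
)
result = hydration_table(vol, visc, cfg, solvent.v1bar)

write_results(dataclasses.asdict(result), out / "hydration.json")

print("T/K      hn(volumetric)  hn(viscometric)")
for row in result.rows:
    hv = f"{row.hn_volumetric:.2f}" if row.hn_volumetric is not None else "  — "
    print(f"{row.temperature:7.2f}  {hv:>13s}  {row.hn_viscometric:14.2f}")
print("viscometric hydration number strictly decreasing with T:",
      result.viscometric_monotone_decreasing)
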