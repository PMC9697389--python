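#!/usr/bin/env python
"""Generate the synthetic measurement tables used by the later stages.

Writes solubility/density/viscosity CSVs (plus the solvent baseline and
the hidden ground truth) for caffeine in 0.1 mol·kg⁻¹ aqueous sodium
salicylate, at the study conditions: five temperatures 293.15–313.15 K,
eight molalities up to 0.105 mol·kg⁻¹, instrument-scale Gaussian noise.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from caffsol import CAFFEINE, generate_density, generate_solubility, generate_viscosity
from caffsol.fixtures import default_ground_truth, ss_solvent_reference
from caffsol.io import write_results
from caffsol.synthetic import DEFAULT_MOLALITIES

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results/synthetic"))
args = parser.parse_args()

truth = default_ground_truth(seed=args.seed)
solvent = ss_solvent_reference()
out = args.out_dir
out.mkdir(parents=True, exist_ok=True)

density = generate_density(truth, solvent, CAFFEINE, DEFAULT_MOLALITIES)
viscosity = generate_viscosity(truth, solvent, CAFFEINE, DEFAULT_MOLALITIES, density)
solubility = generate_solubility(truth, CAFFEINE, truth.temperatures)

pd.DataFrame({
    "molality_mol_kg": density.molality,
    "temperature_K": density.temperature,
    "density_g_cm3": density.density,
}).to_csv(out / "density.csv", index=False)
pd.DataFrame({
    "molality_mol_kg": viscosity.molality,
    "temperature_K": viscosity.temperature,
    "viscosity_mPa_s": viscosity.viscosity,
}).to_csv(out / "viscosity.csv", index=False)
pd.DataFrame({
    "temperature_K": solubility.temperature,
    "solubility_g_per_kg": solubility.solubility,
}).to_csv(out / "solubility.csv", index=False)
pd.DataFrame({
    "temperature_K": solvent.temperatures,
    "rho0_g_cm3": [solvent.rho0_at(t) for t in solvent.temperatures],
    "eta0_mPa_s": [solvent.eta0_at(t) for t in solvent.temperatures],
    "v1bar_cm3_mol": [solvent.v1bar_at(t) for t in solvent.temperatures],
}).to_csv(out / "solvent.csv", index=False)
write_results(dataclasses.asdict(truth), out / "ground_truth.json")

print(f"wrote {len(density)} density rows, {len(viscosity)} viscosity rows and "
      f"{len(solubility)} solubility rows to {out} (seed {args.seed})")
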