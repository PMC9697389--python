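#!/usr/bin/env python
"""Viscometric analysis: Jones–Dole B, structure class, activation chain.

Fits the Jones–Dole line to the synthetic viscosity series from step 01
(recovering the reference B row), classifies the solute from the signs
of B and dB/dT, and evaluates the transition-state activation chain
Δμ₁°≠ → Δμ₂°≠ → (ΔS₂°≠, ΔH₂°≠).
"""

import dataclasses
from pathlib import Path

from caffsol import CAFFEINE, analyze_activation, analyze_viscometrics, analyze_volumetrics
from caffsol.fixtures import ss_solvent_reference
from caffsol.io import read_table, write_results

out = Path("results")
density = read_table(out / "synthetic/density.csv", "density")
viscosity = read_table(out / "synthetic/viscosity.csv", "viscosity")
solvent = ss_solvent_reference()

visc = analyze_viscometrics(viscosity, density, solvent, CAFFEINE)
vol = analyze_volumetrics(density, solvent, CAFFEINE)
v2bar = {T: f.vphi0 for T, f in zip(vol.temperatures, vol.masson)}
act = analyze_activation(visc.B_per_T, v2bar, solvent)

write_results({
    "jones_dole": dataclasses.asdict(visc),
    "activation": dataclasses.asdict(act),
}, out / "viscometrics.json")

print("T/K      B/(dm3/mol)  R2       dmu1     dmu2  (kJ/mol)")
for T in act.temperatures:
    print(f"{T:7.2f}  {visc.B_per_T[T]:10.4f}  {visc.fit_r2_per_T[T]:.5f} "
          f"{act.dmu1_per_T[T]:8.2f} {act.dmu2_per_T[T]:8.2f}")
print(f"dB/dT = {visc.dBdT:+.5f} dm3/mol/K -> {visc.classification}")
print(f"dS2 = {act.dS2:.2f} J/mol/K, dH2 = {act.dH2:.2f} kJ/mol at T_ref = {act.t_ref:.2f} K")
print("dmu2 > dmu1 at every temperature:",
      all(act.dmu2_per_T[T] > act.dmu1_per_T[T] for T in act.temperatures))
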