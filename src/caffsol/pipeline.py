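"""Orchestration: run every stage from one config, with a run manifest.

A run config (YAML or dict) names the input CSVs and options:

.. code-block:: yaml

    solute: {name: caffeine, molar_mass: 194.19}
    inputs:
      solubility: solubility.csv        # optional
      density: density.csv              # optional
      viscosity: viscosity.csv          # optional (needs density)
      solvent: solvent.csv              # required for density/viscosity
    hydration:
      shape_factor: 2.5
      intrinsic_volume: 144.0           # switches on intrinsic-subtraction
    seed: 0

Stages whose inputs are missing are skipped and recorded as such in the
manifest.  Re-running with identical inputs reproduces every output file
byte-identically (all stages are deterministic; the seed only matters to
the synthetic generator).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .core import AlignmentError, SoluteSpec
from .dissolution import analyze_dissolution, solubility_ratio
from .hydration import ElectrostrictionConfig, hydration_table
from .io import read_config, read_table, write_results
from .viscometrics import analyze_activation, analyze_viscometrics
from .volumetrics import analyze_volumetrics, transfer_volume


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    input_digests: dict[str, str]
    seed: int
    package_version: str
    stage_status: dict[str, str] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _solute(cfg: Mapping[str, Any]) -> SoluteSpec:
    spec = cfg.get("solute", {})
    return SoluteSpec(
        name=spec.get("name", "caffeine"),
        molar_mass=float(spec.get("molar_mass", 194.19)),
    )


def run_full(
    config: str | Path | Mapping[str, Any], out_dir: str | Path | None = None
) -> tuple[RunManifest, dict]:
    """Execute every stage the config provides inputs for.

    Returns (manifest, report).  The report is a nested dict with one
    section per stage; if ``out_dir`` is given, the report and manifest
    are also written there as JSON.
    """
    if isinstance(config, (str, Path)):
        base = Path(config).parent
        cfg = read_config(config)
    else:
        base = Path(".")
        cfg = dict(config)
    solute = _solute(cfg)
    inputs = cfg.get("inputs", {})
    paths = {k: (base / v if not Path(v).is_absolute() else Path(v)) for k, v in inputs.items()}
    manifest = RunManifest(
        config=cfg,
        input_digests={k: _sha256(p) for k, p in paths.items() if p.exists()},
        seed=int(cfg.get("seed", 0)),
        package_version=__version__,
    )
    report: dict[str, Any] = {"solute": dataclasses.asdict(solute)}

    solvent = None
    if "solvent" in paths:
        solvent = read_table(paths["solvent"], "solvent")

    if "solubility" in paths:
        table = read_table(paths["solubility"], "solubility")
        thermo = analyze_dissolution(table, solute, float(cfg.get("water_molar_mass", 18.015)))
        report["dissolution"] = dataclasses.asdict(thermo)
        manifest.stage_status["dissolution"] = "ok"
    else:
        manifest.stage_status["dissolution"] = "skipped (no solubility input)"

    vol = None
    if "density" in paths and solvent is not None:
        density = read_table(paths["density"], "density")
        vol = analyze_volumetrics(density, solvent, solute)
        report["volumetrics"] = dataclasses.asdict(vol)
        manifest.stage_status["volumetrics"] = "ok"
    else:
        manifest.stage_status["volumetrics"] = "skipped (no density/solvent input)"

    visc = None
    if "viscosity" in paths and "density" in paths and solvent is not None:
        viscosity = read_table(paths["viscosity"], "viscosity")
        density = read_table(paths["density"], "density")
        visc = analyze_viscometrics(viscosity, density, solvent, solute)
        report["viscometrics"] = dataclasses.asdict(visc)
        if vol is not None:
            v2bar = {T: f.vphi0 for T, f in zip(vol.temperatures, vol.masson)}
            act = analyze_activation(visc.B_per_T, v2bar, solvent)
            report["activation"] = dataclasses.asdict(act)
            manifest.stage_status["activation"] = "ok"
        manifest.stage_status["viscometrics"] = "ok"
    else:
        manifest.stage_status["viscometrics"] = "skipped (no viscosity input)"
        manifest.stage_status.setdefault("activation", "skipped")

    if vol is not None and visc is not None and solvent is not None:
        hcfg_opts = cfg.get("hydration", {})
        if "intrinsic_volume" in hcfg_opts:
            hcfg = ElectrostrictionConfig(
                elect_volume_mode="intrinsic-subtraction",
                intrinsic_volume=float(hcfg_opts["intrinsic_volume"]),
            )
        else:
            hcfg = ElectrostrictionConfig()
        hyd = hydration_table(
            vol,
            visc,
            hcfg,
            solvent.v1bar,
            shape_factor=float(hcfg_opts.get("shape_factor", 2.5)),
        )
        report["hydration"] = dataclasses.asdict(hyd)
        manifest.stage_status["hydration"] = "ok"
    else:
        manifest.stage_status["hydration"] = "skipped (needs volumetrics + viscometrics)"

    if out_dir is not None:
        out = Path(out_dir)
        write_results(report, out / "report.json")
        write_results(dataclasses.asdict(manifest), out / "manifest.json")
    return manifest, report


def compare_systems(report_a: Mapping[str, Any], report_b: Mapping[str, Any],
                    solubility_a=None, solubility_b=None) -> dict:
    """Side-by-side comparison of two runs (e.g. mixed solvent vs water).

    Produces per-temperature solubility ratios (if tables are given),
    transfer volumes V_φ°(a) − V_φ°(b), ΔB, and the dissolution
    thermodynamics of both systems.
    """
    out: dict[str, Any] = {}
    if solubility_a is not None and solubility_b is not None:
        ratios = solubility_ratio(solubility_a, solubility_b)
        out["solubility_ratio"] = ratios
        out["max_solubility_ratio"] = max(ratios.values())
    va, vb = report_a.get("volumetrics"), report_b.get("volumetrics")
    if va and vb:
        ta, tb = list(va["temperatures"]), list(vb["temperatures"])
        common = [t for t in ta if t in tb]
        if not common:
            raise AlignmentError("no overlapping temperatures between runs")
        out["transfer_volume"] = {
            t: transfer_volume(
                va["masson"][ta.index(t)]["vphi0"], vb["masson"][tb.index(t)]["vphi0"]
            )
            for t in common
        }
    ba = report_a.get("viscometrics", {}).get("B_per_T")
    bb = report_b.get("viscometrics", {}).get("B_per_T")
    if ba and bb:
        out["delta_B"] = {
            t: ba[t] - bb[t] for t in ba if t in bb
        }
    for key, rep in (("a", report_a), ("b", report_b)):
        if "dissolution" in rep:
            out.setdefault("dissolution", {})[key] = rep["dissolution"]
    if not out:
        raise AlignmentError("reports share no comparable sections")
    return out
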