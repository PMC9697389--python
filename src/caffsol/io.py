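"""CSV readers, JSON result writers and YAML config handling.

CSV schemas (UTF-8, '.' decimal separator, header mandatory):

====================  ====================================================
kind                  columns
====================  ====================================================
solubility            temperature_K, solubility_g_per_kg
density               molality_mol_kg, temperature_K, density_g_cm3
viscosity             molality_mol_kg, temperature_K, viscosity_mPa_s
solvent               temperature_K, rho0_g_cm3, eta0_mPa_s, v1bar_cm3_mol
====================  ====================================================

Results are written as JSON with ``repr``-faithful floats, so a
write→read round trip reproduces every value bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import (
    DensitySeries,
    SchemaError,
    SolubilityTable,
    SolventReference,
    TableParseError,
    ViscositySeries,
)

SCHEMAS: dict[str, list[str]] = {
    "solubility": ["temperature_K", "solubility_g_per_kg"],
    "density": ["molality_mol_kg", "temperature_K", "density_g_cm3"],
    "viscosity": ["molality_mol_kg", "temperature_K", "viscosity_mPa_s"],
    "solvent": ["temperature_K", "rho0_g_cm3", "eta0_mPa_s", "v1bar_cm3_mol"],
}


def _read_csv(path: str | Path, kind: str) -> pd.DataFrame:
    if kind not in SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}; expected one of {sorted(SCHEMAS)}")
    expected = SCHEMAS[kind]
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: expected columns {expected}; missing {missing}, unexpected {extra}"
        )
    out = {}
    for col in expected:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad.index[bad.isna() & df[col].notna()][0]) + 2  # 1-based + header
        else:
            continue
        raise TableParseError(f"{path}: non-numeric value in column {col!r} at line {row}")
    return pd.DataFrame(out)


def read_table(
    path: str | Path, schema: str
) -> SolubilityTable | DensitySeries | ViscositySeries | SolventReference:
    """Read and validate a measurement CSV of the given ``schema`` kind."""
    df = _read_csv(path, schema)
    if schema == "solubility":
        return SolubilityTable(
            temperature=df["temperature_K"].to_numpy(),
            solubility=df["solubility_g_per_kg"].to_numpy(),
        )
    if schema == "density":
        return DensitySeries(
            molality=df["molality_mol_kg"].to_numpy(),
            temperature=df["temperature_K"].to_numpy(),
            density=df["density_g_cm3"].to_numpy(),
        )
    if schema == "viscosity":
        return ViscositySeries(
            molality=df["molality_mol_kg"].to_numpy(),
            temperature=df["temperature_K"].to_numpy(),
            viscosity=df["viscosity_mPa_s"].to_numpy(),
        )
    return SolventReference(
        description=str(Path(path).stem),
        rho0=dict(zip(df["temperature_K"], df["rho0_g_cm3"])),
        eta0=dict(zip(df["temperature_K"], df["eta0_mPa_s"])),
        v1bar=dict(zip(df["temperature_K"], df["v1bar_cm3_mol"])),
    )


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload = {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
        payload["__type__"] = type(obj).__name__
        return payload
    if isinstance(obj, np.ndarray):
        return [float(x) for x in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_results(results: Any, path: str | Path) -> None:
    """Serialize a result object (dataclass / dict / table) to JSON text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_to_jsonable(results), fh, indent=2, allow_nan=True)
        fh.write("\n")


def read_results(path: str | Path) -> Any:
    """Read back a JSON results file as plain dicts/lists."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def read_config(path: str | Path) -> dict:
    """Load a YAML run configuration."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
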