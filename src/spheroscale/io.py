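"""Serialization of populations, solutions and reports.

Tabular artifacts are CSV (one row per spheroid); large arrays can go
to a compact binary container (NumPy ``.npz``); structured results are
JSON with floats serialized at fixed precision so reports are
byte-stable under identical seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .oxygen import PopulationSolution
from .params import KineticParams, SizeDistributionSpec
from .population import SpheroidPopulation

__all__ = [
    "solutions_to_frame",
    "write_csv",
    "read_csv_groups",
    "write_npz",
    "read_npz",
    "write_json_report",
    "load_external_table",
]

CSV_COLUMNS = [
    "distribution_index",
    "radius_m",
    "mass_kg",
    "socr",
    "B_mol_per_s",
    "phi_percent",
]


def solutions_to_frame(solutions: list[PopulationSolution]) -> pd.DataFrame:
    """Flatten solved populations into one tidy table."""
    frames = []
    for sol in solutions:
        pop = sol.population
        frames.append(
            pd.DataFrame(
                {
                    "distribution_index": pop.spec.index,
                    "radius_m": pop.radii,
                    "mass_kg": pop.masses,
                    "socr": pop.socrs,
                    "B_mol_per_s": sol.B,
                    "phi_percent": sol.phi,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_csv(solutions: list[PopulationSolution], path: str | Path) -> None:
    solutions_to_frame(solutions).to_csv(path, index=False, float_format="%.12g")


def read_csv_groups(path: str | Path):
    """Read a solutions CSV back into (masses, B, index) groups.

    Group mean masses are not stored in the CSV; callers reattach them
    from the generating configuration (or rely on
    :func:`load_external_table` semantics for external data).
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV is missing required columns: {missing}")
    groups = []
    for idx, sub in df.groupby("distribution_index", sort=True):
        groups.append(
            (
                sub["mass_kg"].to_numpy(),
                sub["B_mol_per_s"].to_numpy(),
                sub["phi_percent"].to_numpy(),
                int(idx),
            )
        )
    return groups


def write_npz(solutions: list[PopulationSolution], path: str | Path) -> None:
    """Compact binary container for large-N populations."""
    df = solutions_to_frame(solutions)
    np.savez_compressed(
        path, **{col: df[col].to_numpy() for col in CSV_COLUMNS}
    )


def read_npz(path: str | Path) -> pd.DataFrame:
    with np.load(path) as data:
        return pd.DataFrame({col: data[col] for col in CSV_COLUMNS})


def _round_floats(obj, ndigits: int):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json_report(report: dict, path: str | Path, ndigits: int = 10) -> None:
    """JSON report with floats at fixed precision (byte-stable)."""
    Path(path).write_text(
        json.dumps(_round_floats(report, ndigits), indent=2, sort_keys=True) + "\n"
    )


def load_external_table(path: str | Path, min_group_size: int = 20):
    """Load user-supplied (mass, B) pairs grouped by distribution label.

    Expects delimited text with a header containing at least the
    columns ``group``, ``mass_kg``, ``B_mol_per_s``.  Group mean masses
    default to the within-group mean of ``mass_kg`` unless a
    ``mean_mass_kg`` column supplies them explicitly.

    Returns a list of (masses, B, mean_mass, label) tuples suitable for
    the collapse operations.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = ["group", "mass_kg", "B_mol_per_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"external table is missing required columns {missing}; found {list(df.columns)}"
        )
    if (df["mass_kg"] <= 0).any() or (df["B_mol_per_s"] <= 0).any():
        raise ValueError("mass_kg and B_mol_per_s must be strictly positive")
    groups = []
    import warnings

    for gi, (label, sub) in enumerate(df.groupby("group", sort=True)):
        if len(sub) < min_group_size:
            warnings.warn(
                f"group {label!r} has only {len(sub)} rows (< {min_group_size})"
            )
        if "mean_mass_kg" in sub.columns:
            mean_mass = float(sub["mean_mass_kg"].iloc[0])
        else:
            mean_mass = float(sub["mass_kg"].mean())
        groups.append(
            (
                sub["mass_kg"].to_numpy(),
                sub["B_mol_per_s"].to_numpy(),
                mean_mass,
                gi + 1,
            )
        )
    return groups
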