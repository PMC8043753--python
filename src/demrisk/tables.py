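"""Tabular I/O: species tables, extinction windows, curves, summaries.

Species tables come in two CSV layouts:

* wide — one row per species, with the age-indexed ``survival`` and
  ``fertility`` vectors stored as semicolon-delimited lists inside cells;
* long — a species metadata CSV plus a companion rates CSV with one row
  per (species, age) carrying ``S_x`` and ``m_x``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demography_core import SpeciesParams
from .dynamics import SimConfig
from .risk_regression import ExtinctionWindow
from .scenarios import QuasiExtinctionCurve

__all__ = [
    "SchemaError",
    "species_to_frame",
    "write_species_csv",
    "read_species_csv",
    "write_species_long_csv",
    "read_species_long_csv",
    "write_windows_csv",
    "read_windows_csv",
    "write_curves_csv",
    "read_curves_csv",
    "write_integrals_csv",
    "load_sim_config",
    "dump_sim_config",
]

WIDE_COLUMNS = [
    "name",
    "status",
    "group",
    "mass_kg",
    "alpha",
    "omega",
    "survival",
    "fertility",
    "density",
    "terminal_self_loop",
]


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


def _require_columns(df: pd.DataFrame, needed: list[str], what: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _vec(cell: str, name: str, col: str, row: int) -> np.ndarray:
    try:
        return np.array([float(v) for v in str(cell).split(";")], dtype=float)
    except ValueError as exc:
        raise SchemaError(f"row {row} ({name}): cannot parse {col!r} cell") from exc


def species_to_frame(species: list[SpeciesParams]) -> pd.DataFrame:
    rows = []
    for sp in species:
        rows.append(
            {
                "name": sp.name,
                "status": sp.status,
                "group": sp.group,
                "mass_kg": sp.mass_kg,
                "alpha": sp.alpha,
                "omega": sp.omega,
                "survival": ";".join(format(v, ".12g") for v in sp.survival),
                "fertility": ";".join(format(v, ".12g") for v in sp.fertility),
                "density": sp.density,
                "terminal_self_loop": sp.terminal_self_loop,
            }
        )
    return pd.DataFrame(rows, columns=WIDE_COLUMNS)


def write_species_csv(species: list[SpeciesParams], path: str | Path) -> None:
    species_to_frame(species).to_csv(path, index=False)


def read_species_csv(path: str | Path) -> list[SpeciesParams]:
    df = pd.read_csv(path)
    _require_columns(df, WIDE_COLUMNS, f"species table {path}")
    out = []
    for i, row in df.iterrows():
        out.append(
            SpeciesParams(
                name=str(row["name"]),
                status=str(row["status"]),
                group=str(row["group"]),
                mass_kg=float(row["mass_kg"]),
                alpha=int(row["alpha"]),
                omega=int(row["omega"]),
                survival=_vec(row["survival"], row["name"], "survival", i),
                fertility=_vec(row["fertility"], row["name"], "fertility", i),
                density=float(row["density"]),
                terminal_self_loop=bool(row["terminal_self_loop"]),
            )
        )
    return out


def write_species_long_csv(
    species: list[SpeciesParams], meta_path: str | Path, rates_path: str | Path
) -> None:
    meta = species_to_frame(species).drop(columns=["survival", "fertility"])
    meta.to_csv(meta_path, index=False)
    rows = []
    for sp in species:
        for age in range(sp.omega + 1):
            rows.append(
                {
                    "name": sp.name,
                    "age": age,
                    "S_x": sp.survival[age],
                    "m_x": sp.fertility[age],
                }
            )
    pd.DataFrame(rows).to_csv(rates_path, index=False)


def read_species_long_csv(meta_path: str | Path, rates_path: str | Path) -> list[SpeciesParams]:
    meta = pd.read_csv(meta_path)
    rates = pd.read_csv(rates_path)
    _require_columns(
        meta,
        [c for c in WIDE_COLUMNS if c not in ("survival", "fertility")],
        f"species metadata {meta_path}",
    )
    _require_columns(rates, ["name", "age", "S_x", "m_x"], f"rates table {rates_path}")
    out = []
    for i, row in meta.iterrows():
        name = str(row["name"])
        sub = rates[rates["name"] == name].sort_values("age")
        omega = int(row["omega"])
        if len(sub) != omega + 1 or list(sub["age"]) != list(range(omega + 1)):
            raise SchemaError(
                f"rates for {name}: expected ages 0..{omega}, got {len(sub)} rows"
            )
        out.append(
            SpeciesParams(
                name=name,
                status=str(row["status"]),
                group=str(row["group"]),
                mass_kg=float(row["mass_kg"]),
                alpha=int(row["alpha"]),
                omega=omega,
                survival=sub["S_x"].to_numpy(dtype=float),
                fertility=sub["m_x"].to_numpy(dtype=float),
                density=float(row["density"]),
                terminal_self_loop=bool(row["terminal_self_loop"]),
            )
        )
    return out


def write_windows_csv(windows: list[ExtinctionWindow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"species": w.species, "earliest_ka": w.earliest_ka, "latest_ka": w.latest_ka}
            for w in windows
        ]
    ).to_csv(path, index=False)


def read_windows_csv(path: str | Path) -> list[ExtinctionWindow]:
    df = pd.read_csv(path)
    _require_columns(df, ["species", "earliest_ka", "latest_ka"], f"windows table {path}")
    return [
        ExtinctionWindow(
            species=str(r["species"]),
            earliest_ka=float(r["earliest_ka"]),
            latest_ka=float(r["latest_ka"]),
        )
        for _, r in df.iterrows()
    ]


def write_curves_csv(curves: list[QuasiExtinctionCurve], path: str | Path) -> None:
    """Tidy long format: species, scenario, intensity, pr_eq."""
    rows = []
    for c in curves:
        for x, p in zip(c.intensities, c.pr_eq):
            rows.append(
                {"species": c.species, "scenario": c.kind, "intensity": x, "pr_eq": p}
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_curves_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["species", "scenario", "intensity", "pr_eq"], f"curves {path}")
    return df


def write_integrals_csv(
    integrals: dict[str, dict[str, float]],
    raw_integrals: dict[str, dict[str, float]] | None,
    path: str | Path,
) -> None:
    rows = []
    for scen, by_sp in integrals.items():
        for sp, val in by_sp.items():
            row = {"species": sp, "scenario": scen, "integral": val}
            if raw_integrals is not None:
                row["raw_integral"] = raw_integrals[scen][sp]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def load_sim_config(path: str | Path | None, **overrides) -> SimConfig:
    """SimConfig from a YAML or JSON file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        ) or {}
        unknown = set(data) - set(SimConfig.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return SimConfig(**data)


def dump_sim_config(config: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.__dict__, sort_keys=True))
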