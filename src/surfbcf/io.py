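"""Reading and writing the tabular study inputs and result reports.

Input schema (tidy long CSVs, fixed units):

    chemicals.csv  chem_id,name,log_dmlw,dmlw_source,nominal_cw_ugL
    water.csv      chem_id,time_h,phase,replicate,conc_ugL
    fish.csv       chem_id,time_h,phase,fish_id,mass_g,conc_ugkg
    controls.csv   chem_id,fish_id,conc_ugkg

Optional boolean columns ``below_loq``/``below_lod`` are honoured on
water/fish files. Results are written as CSV and JSON with a stable
column order; non-quantifiable entries (NaN) are rendered as the
sentinel string "nq" on output and parsed back to NaN on input.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    ChemicalProperties,
    ConcentrationRecord,
    DmlwSource,
    Phase,
    StudyDataset,
)

__all__ = ["SchemaError", "read_study", "write_results", "read_results"]

NQ = "nq"  # sentinel for non-quantifiable values in reports

RESULT_COLUMNS = [
    "chem_id", "method",
    "k_u", "k_u_lo", "k_u_hi",
    "k_t", "k_t_lo", "k_t_hi",
    "bcf", "bcf_lo", "bcf_hi",
    "log_dmlw", "diffusion_coeff", "k2", "kb_bcf", "baseline_bcf", "kb_s9",
    "converged", "n_points_used",
]

_REQUIRED = {
    "chemicals": ["chem_id", "name", "log_dmlw", "dmlw_source",
                  "nominal_cw_ugL"],
    "water": ["chem_id", "time_h", "phase", "replicate", "conc_ugL"],
    "fish": ["chem_id", "time_h", "phase", "fish_id", "mass_g", "conc_ugkg"],
    "controls": ["chem_id", "fish_id", "conc_ugkg"],
}


class SchemaError(ValueError):
    """A required column is missing or a row violates the schema."""


def _check_columns(df: pd.DataFrame, kind: str, path) -> None:
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _records(
    df: pd.DataFrame, kind: str, path
) -> list[ConcentrationRecord]:
    value_col = "conc_ugL" if kind == "water" else "conc_ugkg"
    id_col = "replicate" if kind == "water" else "fish_id"
    out = []
    errors = []
    for i, row in df.iterrows():
        try:
            out.append(
                ConcentrationRecord(
                    chem_id=str(row["chem_id"]),
                    time_h=float(row["time_h"]),
                    phase=Phase(str(row["phase"])),
                    sample_id=str(row[id_col]),
                    value=float(row[value_col]),
                    below_loq=bool(row.get("below_loq", False)),
                    below_lod=bool(row.get("below_lod", False)),
                    mass_g=(
                        float(row["mass_g"]) if "mass_g" in row and
                        pd.notna(row["mass_g"]) else None
                    ),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"{path} line {i + 2}: {exc}")
    if errors:
        raise SchemaError("; ".join(errors))
    return out


def read_study(
    chemicals_csv,
    water_csv,
    fish_csv,
    controls_csv=None,
    exposure_end_h: float = 96.0,
    fish_mass_kg: Optional[float] = None,
) -> StudyDataset:
    """Load and validate a study from its four CSV files.

    Unparseable rows are reported with 1-based file line numbers; a
    fish or water record citing an unknown chem_id fails validation in
    :class:`~surfbcf.datatypes.StudyDataset`.
    """
    chem_df = pd.read_csv(chemicals_csv)
    _check_columns(chem_df, "chemicals", chemicals_csv)
    chemicals = []
    for i, row in chem_df.iterrows():
        try:
            nominal = row["nominal_cw_ugL"]
            chemicals.append(
                ChemicalProperties(
                    chem_id=str(row["chem_id"]),
                    name=str(row["name"]),
                    log_dmlw=float(row["log_dmlw"]),
                    nominal_cw=float(nominal) if pd.notna(nominal) else None,
                    dmlw_source=DmlwSource(str(row["dmlw_source"])),
                )
            )
        except ValueError as exc:
            raise SchemaError(
                f"{chemicals_csv} line {i + 2}: {exc}"
            ) from exc

    water_df = pd.read_csv(water_csv)
    _check_columns(water_df, "water", water_csv)
    water = _records(water_df, "water", water_csv)

    fish_df = pd.read_csv(fish_csv)
    _check_columns(fish_df, "fish", fish_csv)
    fish = _records(fish_df, "fish", fish_csv)

    controls: list[ConcentrationRecord] = []
    if controls_csv is not None:
        ctrl_df = pd.read_csv(controls_csv)
        _check_columns(ctrl_df, "controls", controls_csv)
        for i, row in ctrl_df.iterrows():
            try:
                controls.append(
                    ConcentrationRecord(
                        chem_id=str(row["chem_id"]),
                        time_h=0.0,
                        phase=Phase.EXPOSURE,
                        sample_id=str(row["fish_id"]),
                        value=float(row["conc_ugkg"]),
                    )
                )
            except ValueError as exc:
                raise SchemaError(
                    f"{controls_csv} line {i + 2}: {exc}"
                ) from exc

    if fish_mass_kg is None:
        masses = [r.mass_g for r in fish if r.mass_g is not None]
        fish_mass_kg = float(np.mean(masses)) / 1000 if masses else 0.024

    return StudyDataset(
        chemicals=chemicals,
        water=water,
        fish=fish,
        controls=controls,
        exposure_end_h=exposure_end_h,
        fish_mass_kg=fish_mass_kg,
    )


def write_study(dataset: StudyDataset, outdir) -> dict[str, Path]:
    """Write a StudyDataset back to the four-CSV input layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    chem_rows = [
        {
            "chem_id": c.chem_id, "name": c.name, "log_dmlw": c.log_dmlw,
            "dmlw_source": c.dmlw_source.value,
            "nominal_cw_ugL": c.nominal_cw,
        }
        for c in dataset.chemicals
    ]
    paths["chemicals"] = outdir / "chemicals.csv"
    pd.DataFrame(chem_rows).to_csv(paths["chemicals"], index=False)

    def rec_rows(records, value_col, id_col, with_mass):
        rows = []
        for r in records:
            row = {
                "chem_id": r.chem_id, "time_h": r.time_h,
                "phase": r.phase.value, id_col: r.sample_id,
            }
            if with_mass:
                row["mass_g"] = r.mass_g
            row[value_col] = r.value
            row["below_loq"] = r.below_loq
            row["below_lod"] = r.below_lod
            rows.append(row)
        return rows

    paths["water"] = outdir / "water.csv"
    pd.DataFrame(
        rec_rows(dataset.water, "conc_ugL", "replicate", False)
    ).to_csv(paths["water"], index=False)
    paths["fish"] = outdir / "fish.csv"
    pd.DataFrame(
        rec_rows(dataset.fish, "conc_ugkg", "fish_id", True)
    ).to_csv(paths["fish"], index=False)
    paths["controls"] = outdir / "controls.csv"
    pd.DataFrame(
        [
            {"chem_id": r.chem_id, "fish_id": r.sample_id,
             "conc_ugkg": r.value}
            for r in dataset.controls
        ],
        columns=["chem_id", "fish_id", "conc_ugkg"],
    ).to_csv(paths["controls"], index=False)
    return paths


def _render(value) -> object:
    if value is None:
        return NQ
    if isinstance(value, float) and math.isnan(value):
        return NQ
    return value


def write_results(rows: list[dict], path) -> None:
    """Write a per-chemical results report (CSV, and JSON alongside).

    ``rows`` are dicts keyed by :data:`RESULT_COLUMNS` (missing keys
    become "nq"). Numeric values round-trip at full precision through
    the JSON report and to >= 6 significant digits through the CSV.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = [
        {col: _render(row.get(col, float("nan"))) for col in RESULT_COLUMNS}
        for row in rows
    ]
    df = pd.DataFrame(table, columns=RESULT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(table, fh, indent=1, default=float)
        fh.write("\n")


def read_results(path) -> pd.DataFrame:
    """Read a results report; "nq" sentinels come back as NaN."""
    df = pd.read_csv(path, na_values=[NQ], keep_default_na=True)
    return df
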