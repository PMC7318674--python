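"""Readers and writers for the plain-text exchange formats.

Formats
-------
species.csv
    Columns ``species_id,name,range_area_km2,threats`` plus optional
    ``geometry_cells``.  ``threats`` and ``geometry_cells`` are
    semicolon-delimited within a cell.
overlap.csv
    Square matrix with species ids as both header row and first column;
    entry (row i, column j) is the fraction of j's range covered by i.
threats.csv
    Optional long form with columns ``species_id,threat_id``.
config (YAML)
    Keys mirroring :class:`~umbrellapick.datamodel.RunConfig` fields.
priority.csv / summary.json
    Prioritization outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    DataFormatError,
    DataValidationError,
    OverlapMatrix,
    RunConfig,
    SpeciesRecord,
    validate_records,
)

_SPECIES_COLUMNS = ("species_id", "name", "range_area_km2", "threats")


def _split_field(raw: object) -> list[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    text = str(raw).strip()
    if not text:
        return []
    return [tok.strip() for tok in text.split(";") if tok.strip()]


def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read and validate a species table CSV.

    Raises :class:`DataFormatError` for missing columns and
    :class:`DataValidationError` for non-positive areas or duplicate ids.
    """
    df = pd.read_csv(path, dtype={"species_id": str, "name": str})
    missing = [c for c in _SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"species table {path} is missing required column(s): {missing}"
        )
    bad_area = df[~(pd.to_numeric(df["range_area_km2"], errors="coerce") > 0)]
    if len(bad_area):
        raise DataValidationError(
            "non-positive or non-numeric range_area_km2 for species: "
            f"{bad_area['species_id'].tolist()}"
        )
    records: list[SpeciesRecord] = []
    has_geometry = "geometry_cells" in df.columns
    for _, row in df.iterrows():
        geometry = None
        if has_geometry:
            cells = _split_field(row["geometry_cells"])
            if cells:
                try:
                    geometry = frozenset(int(c) for c in cells)
                except ValueError as exc:
                    raise DataFormatError(
                        f"species {row['species_id']!r}: geometry_cells must "
                        f"be semicolon-delimited integers"
                    ) from exc
        records.append(
            SpeciesRecord(
                species_id=str(row["species_id"]),
                name=str(row["name"]),
                range_area=float(row["range_area_km2"]),
                threats=frozenset(_split_field(row["threats"])),
                geometry=geometry,
            )
        )
    validate_records(records)
    return records


def write_species_table(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "species_id": rec.species_id,
                "name": rec.name,
                "range_area_km2": rec.range_area,
                "threats": ";".join(sorted(rec.threats)),
                "geometry_cells": (
                    ";".join(str(c) for c in sorted(rec.geometry))
                    if rec.geometry is not None
                    else ""
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def build_overlap_matrix(records: Sequence[SpeciesRecord]) -> OverlapMatrix:
    """Exact overlap matrix from grid-cell geometries (see datamodel)."""
    return OverlapMatrix.from_geometries(records)


def read_overlap_matrix(
    path: str | Path,
    species_order: Sequence[str],
    areas: Optional[Sequence[float]] = None,
) -> OverlapMatrix:
    """Read a square overlap CSV and align it to ``species_order``.

    Raises on id mismatch (reporting the symmetric difference), on
    entries outside [0, 1] and on a non-unit diagonal; when ``areas``
    are supplied the intersection-area consistency identity is checked.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    file_ids = set(df.index)
    if set(df.columns) != file_ids:
        raise DataFormatError(
            f"overlap matrix {path}: header row and first column disagree"
        )
    want = set(species_order)
    if file_ids != want:
        diff = sorted(file_ids.symmetric_difference(want))
        raise DataValidationError(
            f"overlap matrix ids do not match species table; "
            f"symmetric difference: {diff}"
        )
    df = df.loc[list(species_order), list(species_order)]
    matrix = OverlapMatrix(
        values=df.to_numpy(dtype=float), species_ids=tuple(species_order)
    )
    # entries in the file are quantized (write_overlap_matrix uses 6
    # decimals); allow that much slack in the consistency identity
    matrix.validate(areas=areas, entry_quantum=1e-6)
    return matrix


def write_overlap_matrix(matrix: OverlapMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.values, index=list(matrix.species_ids), columns=list(matrix.species_ids)
    )
    df.to_csv(path, float_format="%.6f")


def read_threats_long(path: str | Path) -> dict[str, frozenset[str]]:
    """Read the optional long-form threat table (species_id, threat_id)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("species_id", "threat_id"):
        if col not in df.columns:
            raise DataFormatError(f"threat table {path} is missing column {col!r}")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["species_id"], set()).add(row["threat_id"])
    return {sid: frozenset(ts) for sid, ts in out.items()}


def write_threats_long(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    rows = [
        {"species_id": rec.species_id, "threat_id": t}
        for rec in records
        for t in sorted(rec.threats)
    ]
    pd.DataFrame(rows, columns=["species_id", "threat_id"]).to_csv(path, index=False)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration mirroring RunConfig fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise DataFormatError(f"config {path} must be a mapping of keys to values")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise DataFormatError(f"config {path}: unknown keys {sorted(unknown)}")
    if "unmanageable_threats" in raw and raw["unmanageable_threats"] is not None:
        raw["unmanageable_threats"] = tuple(raw["unmanageable_threats"])
    return RunConfig(**raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    data = {
        "budget": config.budget,
        "scenario": config.scenario,
        "benefit_denominator": config.benefit_denominator,
        "cost_q": config.cost_q,
        "cost_z": config.cost_z,
        "greedy_budget_rule": config.greedy_budget_rule,
        "benefit_threshold": config.benefit_threshold,
        "seed": config.seed,
        "unmanageable_threats": list(config.unmanageable_threats),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def write_priority_list(result, path: str | Path) -> None:
    """Write a greedy selection as priority.csv.

    Columns: rank, species_id, category, marginal_benefit, cost,
    cumulative_spend, n_species_newly_benefitting.  Header is always
    present; floats are printed at 6 decimals.
    """
    rows = []
    for step in result.steps:
        rows.append(
            {
                "rank": step.rank,
                "species_id": step.species_id,
                "category": result.categories.get(step.species_id, ""),
                "marginal_benefit": step.marginal_benefit,
                "cost": step.cost,
                "cumulative_spend": step.cumulative_spend,
                "n_species_newly_benefitting": step.n_newly_benefitting,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "rank",
            "species_id",
            "category",
            "marginal_benefit",
            "cost",
            "cumulative_spend",
            "n_species_newly_benefitting",
        ],
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_summary(summary: dict, path: str | Path) -> None:
    """Write the run summary JSON (sorted keys for byte-stable output)."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
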