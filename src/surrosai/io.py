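"""File formats: assessment CSV, sparse-triplet occurrence matrices with a
JSON grid sidecar, abiotic layer CSV, ranking CSV.

All formats are plain text (UTF-8, comma-delimited, dot decimal) so runs
diff cleanly. The occurrence interchange format is a triplet CSV
``species,cell,value`` next to a ``<stem>.grid.json`` sidecar carrying
grid shape, cell size, species index and the included-cell mask.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .grid import AbioticLayer, Grid, OccurrenceMatrix
from .prioritize import PriorityRanking
from .redlist import AssessmentRecord

__all__ = [
    "read_assessments",
    "write_assessments",
    "read_occurrence_matrix",
    "write_occurrence_matrix",
    "read_abiotic_layer",
    "write_abiotic_layer",
    "write_ranking",
    "read_ranking",
]

_ASSESSMENT_COLUMNS = [
    "species_id", "group", "category", "tags", "threats", "habitats", "assessment_year",
]


def _join(values) -> str:
    return ";".join(sorted(values))


def _split(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(str(cell).split(";"))


def write_assessments(records: list[AssessmentRecord], path: str | Path) -> None:
    rows = [
        {
            "species_id": r.species_id,
            "group": r.group,
            "category": r.category,
            "tags": _join(r.tags),
            "threats": _join(r.threats),
            "habitats": _join(r.habitats),
            "assessment_year": "" if r.assessment_year is None else r.assessment_year,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_ASSESSMENT_COLUMNS).to_csv(path, index=False)


def read_assessments(path: str | Path) -> list[AssessmentRecord]:
    """Parse an assessment CSV; malformed rows are reported with line numbers."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_ASSESSMENT_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            year = getattr(row, "assessment_year", "")
            records.append(
                AssessmentRecord(
                    species_id=row.species_id,
                    group=row.group,
                    category=row.category,
                    tags=_split(getattr(row, "tags", "")),
                    threats=_split(getattr(row, "threats", "")),
                    habitats=_split(getattr(row, "habitats", "")),
                    assessment_year=int(year) if year not in ("", None) else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return records


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".grid.json") if path.suffix != ".csv" \
        else path.with_suffix(".grid.json")


def write_occurrence_matrix(m: OccurrenceMatrix, path: str | Path) -> None:
    path = Path(path)
    coo = m.matrix.tocoo()
    pd.DataFrame(
        {"species": [m.species_ids[i] for i in coo.row], "cell": coo.col, "value": 1}
    ).sort_values(["species", "cell"]).to_csv(path, index=False)
    meta = {
        "n_rows": m.grid.n_rows,
        "n_cols": m.grid.n_cols,
        "cell_size": m.grid.cell_size,
        "species_ids": m.species_ids,
        "excluded_cells": np.flatnonzero(~m.included).tolist(),
        "flagged_empty": m.flagged_empty,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_occurrence_matrix(path: str | Path) -> OccurrenceMatrix:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    grid = Grid(meta["n_rows"], meta["n_cols"], meta.get("cell_size", 0.5))
    species_ids = meta["species_ids"]
    index = {s: i for i, s in enumerate(species_ids)}
    df = pd.read_csv(path)
    unknown = set(df["species"]) - set(index)
    if unknown:
        raise ValueError(f"{path}: species not in sidecar index: {sorted(unknown)[:5]}")
    if len(df) and (df["cell"].min() < 0 or df["cell"].max() >= grid.n_cells):
        raise ValueError(f"{path}: cell ids outside the {grid.n_cells}-cell grid")
    matrix = sp.csr_matrix(
        (np.ones(len(df), dtype=np.int8),
         (df["species"].map(index).to_numpy(), df["cell"].to_numpy())),
        shape=(len(species_ids), grid.n_cells),
    )
    included = np.ones(grid.n_cells, dtype=bool)
    included[np.asarray(meta.get("excluded_cells", []), dtype=np.int64)] = False
    out = OccurrenceMatrix(grid=grid, matrix=matrix, species_ids=species_ids, included=included)
    out.flagged_empty = list(meta.get("flagged_empty", []))
    return out


def write_abiotic_layer(layer: AbioticLayer, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cell": np.arange(layer.grid.n_cells),
            "value": ["" if m else repr(float(v)) for v, m in zip(layer.values, layer.missing)],
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps({"n_rows": layer.grid.n_rows, "n_cols": layer.grid.n_cols,
                    "cell_size": layer.grid.cell_size})
    )


def read_abiotic_layer(path: str | Path) -> AbioticLayer:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    grid = Grid(meta["n_rows"], meta["n_cols"], meta.get("cell_size", 0.5))
    df = pd.read_csv(path, dtype={"cell": np.int64, "value": str}, keep_default_na=False)
    if len(df) != grid.n_cells or not np.array_equal(df["cell"], np.arange(grid.n_cells)):
        raise ValueError(f"{path}: layer must list every cell id exactly once, in order")
    missing = (df["value"] == "").to_numpy()
    values = np.zeros(grid.n_cells)
    values[~missing] = [float(v) for v in df.loc[~missing, "value"]]
    return AbioticLayer(grid=grid, values=values, missing=missing)


def write_ranking(r: PriorityRanking, path: str | Path) -> None:
    pd.DataFrame(
        {"rank": np.arange(1, len(r) + 1), "cell_id": r.cells}
    ).to_csv(path, index=False)


def read_ranking(path: str | Path, algorithm: str = "UNKNOWN") -> PriorityRanking:
    df = pd.read_csv(path)
    return PriorityRanking(cells=df["cell_id"].to_numpy(), algorithm=algorithm)
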