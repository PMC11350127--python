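"""Validated readers and writers for the pipeline's tabular formats.

Formats are deliberately plain: TSV genotype tables (one row per line, one
``Chr{k}`` or marker column, alleles ``Col``/``Ler``), CSV per-plant
phenotype tables, CSV marker maps and JSON reports.  Readers validate
schemas and report malformed rows with their line numbers; writers produce
stable column/key ordering so outputs can be diffed and hashed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .breeding import MarkerMap, RecombinantGenotype
from .panel import ALLELES, CslGenotype, frame_to_genotypes, panel_frame


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Read a genotype TSV (``line_id`` + allele columns) with validation.

    Every allele value must be ``Col`` or ``Ler``; offending cells are
    reported with their row number (1-based, excluding the header) and
    column name.  Duplicate line ids are rejected.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "line_id" not in frame.columns:
        raise ValueError(f"{path}: missing 'line_id' column")
    dup = frame["line_id"][frame["line_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicated line_id values: {sorted(set(dup))}")
    allele_cols = [c for c in frame.columns if c != "line_id"]
    errors = []
    for col in allele_cols:
        bad = ~frame[col].isin(ALLELES)
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(
                f"row {i + 1}, column {col!r}: invalid allele "
                f"{frame[col].iloc[i]!r} (expected Col or Ler)"
            )
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors[:10]))
    return frame.set_index("line_id")


def write_genotypes(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a genotype table as TSV (inverse of :func:`read_genotypes`)."""
    out = frame.copy()
    out.index.name = "line_id"
    out.to_csv(path, sep="\t")


def write_csl_panel(genotypes: Sequence[CslGenotype], path: str | Path) -> None:
    write_genotypes(panel_frame(genotypes), path)


def read_csl_panel(path: str | Path) -> dict[str, CslGenotype]:
    return frame_to_genotypes(read_genotypes(path))


def write_recombinant_panel(
    lines: Sequence[RecombinantGenotype], marker_map: MarkerMap, path: str | Path
) -> None:
    from .breeding import panel_to_frame

    write_genotypes(panel_to_frame(lines, marker_map), path)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a per-plant phenotype CSV (line_id, block, row, col, trait, value)."""
    frame = pd.read_csv(path)
    required = {"line_id", "block", "row", "col", "trait", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def write_phenotypes(records: pd.DataFrame, path: str | Path) -> None:
    cols = ["line_id", "block", "row", "col", "trait", "value"]
    records[cols].to_csv(path, index=False)


def read_map(path: str | Path) -> MarkerMap:
    """Read a marker map CSV (``marker, chrom, cM[, bp]``), validating order."""
    frame = pd.read_csv(path)
    return MarkerMap(frame)  # MarkerMap validates sortedness and columns


def write_map(marker_map: MarkerMap, path: str | Path) -> None:
    marker_map.frame.to_csv(path, index=False)


def _jsonify(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report(results: Mapping, path: str | Path) -> None:
    """Write a JSON report with sorted keys (stable for hashing/diffing)."""
    with open(path, "w") as fh:
        json.dump(_jsonify(results), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
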