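"""File formats: genotype CSV, phenotype CSV, map/scan TSVs, truth sidecars.

The genotype CSV follows the de-facto cross-file layout of common QTL
software: a header row of marker names (first cell is the genotype-id
column name), two optional annotation rows (``chrom`` and ``cM``) and one
row per genotype.  Missing calls are read from ``NA``, ``-`` or empty
cells and written as ``NA``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abh import AbhMatrix, from_dataframe

__all__ = [
    "read_genotype_csv",
    "read_raw_genotype_csv",
    "write_genotype_csv",
    "read_phenotype_csv",
    "write_phenotype_csv",
    "write_truth_yaml",
    "write_tsv",
]

_ANNOT_CHROM = {"chrom", "chromosome"}
_ANNOT_CM = {"cm", "pos", "position"}


def read_genotype_csv(path: str | Path) -> AbhMatrix:
    """Read an ABH genotype CSV (markers as columns, optional map rows)."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    markers = header[1:]
    if len(set(markers)) != len(markers):
        raise ValueError(f"{path}: duplicate marker IDs in header")
    width = len(header)
    chrom = cm = None
    body_start = 1
    for row in rows[1:3]:
        tag = row[0].strip().lower() if row else ""
        if tag in _ANNOT_CHROM:
            chrom = np.asarray(row[1:], dtype=object)
            body_start += 1
        elif tag in _ANNOT_CM:
            cm = np.asarray([float(v) for v in row[1:]], dtype=float)
            body_start += 1
    ids = []
    data = []
    for i, row in enumerate(rows[body_start:], start=body_start + 1):
        if not row:
            continue
        if len(row) != width:
            raise ValueError(f"{path}: ragged row {i} ({len(row)} fields, expected {width})")
        ids.append(row[0])
        data.append(row[1:])
    df = pd.DataFrame(data, index=ids, columns=markers)
    if chrom is not None and cm is None:
        raise ValueError(f"{path}: chromosome row present but cM row missing")
    if cm is not None and chrom is None:
        raise ValueError(f"{path}: cM row present but chromosome row missing")
    df = df.replace({"": "NA", "-": "NA"})
    return from_dataframe(df, chromosome=chrom, position_cm=cm)


def read_raw_genotype_csv(
    path: str | Path, parent1: str, parent2: str
):
    """Read a raw biallelic genotype CSV (two-letter calls) with parent rows.

    Same layout as the ABH dialect but cells hold calls like ``GG``/``GT``;
    the rows named ``parent1`` and ``parent2`` become the reference parents.
    Returns a :class:`ryeqtl.qc.RawGenotypeMatrix` ready for
    :func:`ryeqtl.qc.encode_abh`.
    """
    from .qc import RawGenotypeMatrix, _parse_call

    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    markers = header[1:]
    if len(set(markers)) != len(markers):
        raise ValueError(f"{path}: duplicate marker IDs in header")
    body = {}
    for i, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise ValueError(f"{path}: ragged row {i}")
        body[row[0]] = row[1:]
    for parent in (parent1, parent2):
        if parent not in body:
            raise ValueError(f"{path}: parent row {parent!r} missing")
    offspring = [gid for gid in body if gid not in (parent1, parent2)]
    calls = np.asarray([body[g] for g in offspring], dtype=object)
    for gid in body:  # validate every call early, naming the offender
        for marker, cell in zip(markers, body[gid]):
            try:
                _parse_call(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: invalid call at row {gid!r}, column {marker!r}"
                ) from exc
    return RawGenotypeMatrix(
        calls=calls,
        genotype_ids=np.asarray(offspring, dtype=object),
        marker_ids=np.asarray(markers, dtype=object),
        parent1_calls=np.asarray(body[parent1], dtype=object),
        parent2_calls=np.asarray(body[parent2], dtype=object),
    )


def write_genotype_csv(abh: AbhMatrix, path: str | Path) -> None:
    path = Path(path)
    df = abh.to_dataframe()
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", *df.columns])
        if abh.has_map:
            writer.writerow(["chrom", *abh.chromosome])
            writer.writerow(["cM", *(repr(float(v)) for v in abh.position_cm)])
        for gid, row in zip(df.index, df.to_numpy()):
            writer.writerow([gid, *row])


def read_phenotype_csv(path: str | Path) -> pd.DataFrame:
    """Long-format phenotype table: genotype, location, replicate, trait, value."""
    df = pd.read_csv(path, dtype={"genotype": str, "location": str, "replicate": str})
    required = {"genotype", "location", "replicate", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {sorted(missing)}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def write_phenotype_csv(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {
            k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__
        }
    return obj


def write_truth_yaml(truth: dict, path: str | Path) -> None:
    """Truth-record sidecar (seed, planted effects, realized frequencies)."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(json.loads(json.dumps(_jsonable(truth))), fh, sort_keys=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
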