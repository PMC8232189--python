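"""ABH genotype matrix: the central exchange object of the toolkit.

An F2 intercross genotype is coded per marker as ``A`` (homozygous for the
parent-1 allele), ``H`` (heterozygous), ``B`` (homozygous for the parent-2
allele) or missing.  Internally calls are stored as a compact ``int8`` array
using the codes below; the string representation is used at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CODE_A: int = 0
CODE_H: int = 1
CODE_B: int = 2
CODE_MISSING: int = -1

STATE_TO_CODE = {"A": CODE_A, "H": CODE_H, "B": CODE_B}
CODE_TO_STATE = {CODE_A: "A", CODE_H: "H", CODE_B: "B", CODE_MISSING: "NA"}

#: codominant dosage (copies of the B allele) per call code
_CD_LOOKUP = np.array([0.0, 1.0, 2.0])
#: heterozygote indicator per call code
_D_LOOKUP = np.array([0.0, 1.0, 0.0])


@dataclass
class AbhMatrix:
    """Genotypes x markers matrix of {A, H, B, missing} calls.

    Parameters
    ----------
    calls
        ``int8`` array of shape ``(n_genotypes, n_markers)`` with values in
        ``{0, 1, 2, -1}`` (A, H, B, missing).
    genotype_ids, marker_ids
        Unique identifiers for rows and columns.
    chromosome, position_cm
        Optional per-marker map assignment (chromosome name and centimorgan
        position).  Both or neither must be present.
    phase
        Optional phased haplotypes of shape ``(n_genotypes, 2, n_markers)``
        with parental-origin alleles 0 (parent 1) / 1 (parent 2).  Populated
        by the simulator; required for simulated selfing.
    """

    calls: np.ndarray
    genotype_ids: np.ndarray
    marker_ids: np.ndarray
    chromosome: np.ndarray | None = None
    position_cm: np.ndarray | None = None
    phase: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.genotype_ids = np.asarray(self.genotype_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D genotypes x markers array")
        n, m = self.calls.shape
        if len(self.genotype_ids) != n:
            raise ValueError(f"{len(self.genotype_ids)} genotype ids for {n} rows")
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} columns")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker ids must be unique")
        if len(set(self.genotype_ids)) != n:
            raise ValueError("genotype ids must be unique")
        bad = ~np.isin(self.calls, (CODE_A, CODE_H, CODE_B, CODE_MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {A, H, B, missing}")
        if (self.chromosome is None) != (self.position_cm is None):
            raise ValueError("chromosome and position_cm must be given together")
        if self.chromosome is not None:
            self.chromosome = np.asarray(self.chromosome, dtype=object)
            self.position_cm = np.asarray(self.position_cm, dtype=float)
            if len(self.chromosome) != m or len(self.position_cm) != m:
                raise ValueError("map annotation length does not match markers")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=np.int8)
            if self.phase.shape != (n, 2, m):
                raise ValueError("phase must have shape (n_genotypes, 2, n_markers)")

    # ------------------------------------------------------------------
    @property
    def n_genotypes(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def has_map(self) -> bool:
        return self.chromosome is not None

    def marker_index(self, marker: str) -> int:
        idx = np.nonzero(self.marker_ids == marker)[0]
        if idx.size == 0:
            raise KeyError(f"unknown marker {marker!r}")
        return int(idx[0])

    def genotype_index(self, genotype: str) -> int:
        idx = np.nonzero(self.genotype_ids == genotype)[0]
        if idx.size == 0:
            raise KeyError(f"unknown genotype {genotype!r}")
        return int(idx[0])

    # ------------------------------------------------------------------
    def cd_matrix(self) -> np.ndarray:
        """Codominant 0/1/2 dosage coding with ``NaN`` for missing calls."""
        out = np.where(self.calls >= 0, self.calls, 0).astype(float)
        out[self.calls == CODE_MISSING] = np.nan
        return out

    def d_matrix(self) -> np.ndarray:
        """Dominant 0/1/0 heterozygote-indicator coding, ``NaN`` for missing."""
        out = np.where(self.calls == CODE_H, 1.0, 0.0)
        out[self.calls == CODE_MISSING] = np.nan
        return out

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return (self.calls == CODE_MISSING).mean(axis=0)

    def genotype_counts(self) -> pd.DataFrame:
        """Per-marker counts of A, H, B and missing calls."""
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "n_A": (self.calls == CODE_A).sum(axis=0),
                "n_H": (self.calls == CODE_H).sum(axis=0),
                "n_B": (self.calls == CODE_B).sum(axis=0),
                "n_missing": (self.calls == CODE_MISSING).sum(axis=0),
            }
        )

    # ------------------------------------------------------------------
    def take_markers(self, index: Sequence[int] | np.ndarray) -> "AbhMatrix":
        index = np.asarray(index, dtype=int)
        return AbhMatrix(
            calls=self.calls[:, index],
            genotype_ids=self.genotype_ids,
            marker_ids=self.marker_ids[index],
            chromosome=None if self.chromosome is None else self.chromosome[index],
            position_cm=None if self.position_cm is None else self.position_cm[index],
            phase=None if self.phase is None else self.phase[:, :, index],
        )

    def take_genotypes(self, index: Sequence[int] | np.ndarray) -> "AbhMatrix":
        index = np.asarray(index, dtype=int)
        return AbhMatrix(
            calls=self.calls[index],
            genotype_ids=self.genotype_ids[index],
            marker_ids=self.marker_ids,
            chromosome=self.chromosome,
            position_cm=self.position_cm,
            phase=None if self.phase is None else self.phase[index],
        )

    def drop_markers(self, markers: Iterable[str]) -> "AbhMatrix":
        drop = set(markers)
        keep = [i for i, m in enumerate(self.marker_ids) if m not in drop]
        return self.take_markers(keep)

    def drop_genotypes(self, genotypes: Iterable[str]) -> "AbhMatrix":
        drop = set(genotypes)
        keep = [i for i, g in enumerate(self.genotype_ids) if g not in drop]
        return self.take_genotypes(keep)

    def copy(self) -> "AbhMatrix":
        return AbhMatrix(
            calls=self.calls.copy(),
            genotype_ids=self.genotype_ids.copy(),
            marker_ids=self.marker_ids.copy(),
            chromosome=None if self.chromosome is None else self.chromosome.copy(),
            position_cm=None if self.position_cm is None else self.position_cm.copy(),
            phase=None if self.phase is None else self.phase.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """String representation (A/H/B/NA), genotypes as rows."""
        data = np.empty(self.calls.shape, dtype=object)
        for code, state in CODE_TO_STATE.items():
            data[self.calls == code] = state
        return pd.DataFrame(data, index=self.genotype_ids, columns=self.marker_ids)

    def __eq__(self, other: object) -> bool:  # bit-level equality, for determinism tests
        if not isinstance(other, AbhMatrix):
            return NotImplemented
        same_map = (
            (self.chromosome is None and other.chromosome is None)
            or (
                self.chromosome is not None
                and other.chromosome is not None
                and np.array_equal(self.chromosome, other.chromosome)
                and np.array_equal(self.position_cm, other.position_cm)
            )
        )
        return (
            np.array_equal(self.calls, other.calls)
            and np.array_equal(self.genotype_ids, other.genotype_ids)
            and np.array_equal(self.marker_ids, other.marker_ids)
            and same_map
        )


def from_dataframe(
    df: pd.DataFrame,
    chromosome: np.ndarray | None = None,
    position_cm: np.ndarray | None = None,
) -> AbhMatrix:
    """Build an :class:`AbhMatrix` from a string-coded DataFrame."""
    calls = np.full(df.shape, CODE_MISSING, dtype=np.int8)
    values = df.to_numpy(dtype=object)
    for state, code in STATE_TO_CODE.items():
        calls[values == state] = code
    known = np.isin(values, ("A", "H", "B", "NA", "-", "", None)) | pd.isna(
        values.astype(object)
    )
    if not known.all():
        r, c = np.nonzero(~known)
        raise ValueError(
            f"invalid genotype symbol {values[r[0], c[0]]!r} at row "
            f"{df.index[r[0]]!r}, column {df.columns[c[0]]!r}"
        )
    return AbhMatrix(
        calls=calls,
        genotype_ids=np.asarray(df.index, dtype=object),
        marker_ids=np.asarray(df.columns, dtype=object),
        chromosome=chromosome,
        position_cm=position_cm,
    )
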