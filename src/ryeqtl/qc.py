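"""Marker quality control for an F2 intercross SNP matrix.

The processing chain mirrors standard biparental-population practice:
recode raw biallelic calls against the two parents (ABH), drop markers with
too many missing values, collapse perfectly correlated (redundant) markers
to one representative, impute isolated missing calls from agreeing map
flanks, test every marker for segregation distortion against the Mendelian
1:2:1 expectation, profile allele frequencies along the chromosomes, and
screen for inter-chromosome marker correlation that would betray
multivalent (co-segregating) chromosome sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .abh import CODE_A, CODE_B, CODE_H, CODE_MISSING, AbhMatrix

__all__ = [
    "RawGenotypeMatrix",
    "EncodeReport",
    "RedundancyGroups",
    "ImputeReport",
    "encode_abh",
    "filter_missing",
    "collapse_redundant",
    "impute_by_flanks",
    "distortion_scan",
    "allele_frequency_profile",
    "multivalent_screen",
    "find_duplicate_genotypes",
    "raw_from_abh",
]

_MISSING_TOKENS = {"NA", "-", "", None}


@dataclass
class RawGenotypeMatrix:
    """Biallelic two-letter calls (e.g. ``GG``/``GT``/``TT``) plus parents."""

    calls: np.ndarray  # (n_genotypes, n_markers) of str
    genotype_ids: np.ndarray
    marker_ids: np.ndarray
    parent1_calls: np.ndarray  # (n_markers,) of str
    parent2_calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=object)
        self.genotype_ids = np.asarray(self.genotype_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.parent1_calls = np.asarray(self.parent1_calls, dtype=object)
        self.parent2_calls = np.asarray(self.parent2_calls, dtype=object)
        n, m = self.calls.shape
        if len(self.marker_ids) != m or len(set(self.marker_ids)) != m:
            raise ValueError("marker ids must be unique and match the call matrix")
        if len(self.genotype_ids) != n:
            raise ValueError("genotype ids must match the call matrix")
        if len(self.parent1_calls) != m or len(self.parent2_calls) != m:
            raise ValueError("both parent rows must cover every marker")


@dataclass
class EncodeReport:
    """Book-keeping from ABH encoding."""

    dropped_ambiguous_parents: list[str] = field(default_factory=list)
    dropped_non_segregating: list[str] = field(default_factory=list)
    unexpected_allele_calls: int = 0


def _parse_call(call) -> tuple[str, str] | None:
    """Two alleles of a raw call, or None when missing."""
    if call in _MISSING_TOKENS or (isinstance(call, float) and np.isnan(call)):
        return None
    s = str(call).strip()
    if s.upper() in {"NA", "-", ""}:
        return None
    if len(s) != 2:
        raise ValueError(f"malformed biallelic call {call!r}")
    return s[0], s[1]


def encode_abh(raw: RawGenotypeMatrix) -> tuple[AbhMatrix, EncodeReport]:
    """Recode raw biallelic calls to A/H/B against the two parents.

    A call equal to parent 1's homozygous allele becomes A, equal to
    parent 2's becomes B, one of each becomes H.  When one parent is
    missing or heterozygous the other is used as reference (the opposite
    offspring homozygote defines the missing parent's allele).  Markers
    where both parents are heterozygous and/or missing are dropped, as are
    markers that do not segregate among the offspring.
    """
    n, m = raw.calls.shape
    report = EncodeReport()
    keep: list[int] = []
    coded = np.full((n, m), CODE_MISSING, dtype=np.int8)
    for j in range(m):
        p1 = _parse_call(raw.parent1_calls[j])
        p2 = _parse_call(raw.parent2_calls[j])
        a1 = p1[0] if p1 is not None and p1[0] == p1[1] else None
        a2 = p2[0] if p2 is not None and p2[0] == p2[1] else None
        if a1 is None and a2 is None:
            report.dropped_ambiguous_parents.append(raw.marker_ids[j])
            continue
        # resolve the unknown parental allele from the reference parent and
        # the offspring: any offspring allele differing from the reference
        # belongs to the other parent
        if a1 is None or a2 is None:
            ref = a1 if a1 is not None else a2
            other = None
            for i in range(n):
                c = _parse_call(raw.calls[i, j])
                if c is None:
                    continue
                for allele in c:
                    if allele != ref:
                        other = allele
                        break
                if other is not None:
                    break
            if a1 is None:
                a1 = other
            else:
                a2 = other
        if a1 is None or a2 is None or a1 == a2:
            # offspring monomorphic for the reference allele, or identical
            # parental alleles: nothing segregates
            report.dropped_non_segregating.append(raw.marker_ids[j])
            continue
        col = np.full(n, CODE_MISSING, dtype=np.int8)
        for i in range(n):
            c = _parse_call(raw.calls[i, j])
            if c is None:
                continue
            x, y = c
            if x == a1 and y == a1:
                col[i] = CODE_A
            elif x == a2 and y == a2:
                col[i] = CODE_B
            elif {x, y} == {a1, a2}:
                col[i] = CODE_H
            else:
                report.unexpected_allele_calls += 1
        present = col[col != CODE_MISSING]
        if present.size == 0 or (present == present[0]).all():
            report.dropped_non_segregating.append(raw.marker_ids[j])
            continue
        coded[:, j] = col
        keep.append(j)
    keep_arr = np.asarray(keep, dtype=int)
    abh = AbhMatrix(
        calls=coded[:, keep_arr],
        genotype_ids=raw.genotype_ids,
        marker_ids=raw.marker_ids[keep_arr],
    )
    return abh, report


def filter_missing(abh: AbhMatrix, max_missing_fraction: float = 0.10) -> AbhMatrix:
    """Retain markers whose missing fraction is at most the threshold."""
    keep = np.nonzero(abh.missing_fraction() <= max_missing_fraction)[0]
    return abh.take_markers(keep)


# ----------------------------------------------------------------------
# Redundancy


@dataclass
class RedundancyGroups:
    """Partition of markers into |r| = 1 groups with chosen representatives."""

    groups: list[list[str]]
    representatives: list[str]

    @property
    def n_unique(self) -> int:
        return len(self.groups)

    def group_of(self, marker: str) -> list[str]:
        for grp in self.groups:
            if marker in grp:
                return grp
        return [marker]


def pairwise_complete_correlation(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns using pairwise-complete rows.

    ``x`` is a float matrix with NaN for missing.  Pairs with fewer than two
    shared observations or zero variance yield NaN.
    """
    mask = np.isfinite(x)
    x0 = np.where(mask, x, 0.0)
    m = mask.astype(float)
    n = m.T @ m
    sx = x0.T @ m
    sxy = x0.T @ x0
    sxx = (x0 * x0).T @ m
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx * sx
        denom = np.sqrt(varx * varx.T)
        r = cov / denom
    r[n < 2] = np.nan
    return r


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def collapse_redundant(
    abh: AbhMatrix, tol: float = 1e-12
) -> tuple[AbhMatrix, RedundancyGroups]:
    """Collapse markers with |correlation| = 1 to one representative each.

    Correlation is computed on codominant 0/1/2 codes over pairwise-complete
    entries; groups are formed transitively over |r| = 1 edges and the
    representative is the member with the fewest missing calls (input order
    breaks ties).
    """
    if abh.n_genotypes < 2:
        raise ValueError("need at least two genotypes")
    r = pairwise_complete_correlation(abh.cd_matrix())
    m = abh.n_markers
    uf = _UnionFind(m)
    close = np.abs(r) >= 1.0 - tol
    ii, jj = np.nonzero(np.triu(np.nan_to_num(close, nan=False), k=1))
    for i, j in zip(ii, jj):
        uf.union(int(i), int(j))
    members: dict[int, list[int]] = {}
    for i in range(m):
        members.setdefault(uf.find(i), []).append(i)
    missing = (abh.calls == CODE_MISSING).sum(axis=0)
    groups: list[list[str]] = []
    reps: list[int] = []
    for root in sorted(members):
        grp = members[root]
        rep = min(grp, key=lambda i: (missing[i], i))
        groups.append([abh.marker_ids[i] for i in grp])
        reps.append(rep)
    reps_sorted = sorted(reps)
    unique = abh.take_markers(reps_sorted)
    rg = RedundancyGroups(
        groups=groups, representatives=[abh.marker_ids[i] for i in reps]
    )
    return unique, rg


# ----------------------------------------------------------------------
# Imputation


@dataclass
class ImputeReport:
    n_flank_filled: int = 0
    n_second_pass_filled: int = 0


def impute_by_flanks(abh: AbhMatrix) -> tuple[AbhMatrix, ImputeReport]:
    """Fill missing calls whose nearest same-chromosome flanks agree.

    First pass: a missing call is set to the shared state of its nearest
    non-missing left and right neighbours (same genotype, same chromosome)
    when the two agree.  Calls unresolved by flanks (disagreeing flanks or
    chromosome ends) are filled in a second pass with the marker's modal
    state; the number of second-pass fills is reported so users can audit.
    """
    if not abh.has_map:
        raise ValueError("imputation requires a chromosome/position annotation")
    out = abh.copy()
    report = ImputeReport()
    for chrom in dict.fromkeys(abh.chromosome):
        cols = np.nonzero(abh.chromosome == chrom)[0]
        pos = abh.position_cm[cols]
        if (np.diff(pos) < 0).any():
            raise ValueError(f"markers on {chrom} are not ordered by position")
        block = out.calls[:, cols].astype(float)
        block[block == CODE_MISSING] = np.nan
        df = pd.DataFrame(block)
        left = df.ffill(axis=1).to_numpy()
        right = df.bfill(axis=1).to_numpy()
        fill = np.isnan(block) & np.isfinite(left) & np.isfinite(right) & (left == right)
        block[fill] = left[fill]
        report.n_flank_filled += int(fill.sum())
        filled = np.where(np.isnan(block), CODE_MISSING, block).astype(np.int8)
        out.calls[:, cols] = filled
    # second pass: per-marker modal state
    for j in range(out.n_markers):
        col = out.calls[:, j]
        miss = col == CODE_MISSING
        if not miss.any():
            continue
        counts = [(col == c).sum() for c in (CODE_A, CODE_H, CODE_B)]
        if max(counts) == 0:
            continue  # fully missing marker stays missing
        modal = int(np.argmax(counts))  # ties break in A < H < B order
        out.calls[miss, j] = modal
        report.n_second_pass_filled += int(miss.sum())
    return out, report


# ----------------------------------------------------------------------
# Distortion and frequencies


def distortion_counts(n_a: int, n_h: int, n_b: int) -> tuple[float, float]:
    """Chi-square statistic and p-value of counts against 1:2:1 (df = 2)."""
    n = n_a + n_h + n_b
    if n == 0:
        raise ValueError("no non-missing calls")
    expected = np.array([n / 4.0, n / 2.0, n / 4.0])
    chi2, p = stats.chisquare([n_a, n_h, n_b], f_exp=expected)
    return float(chi2), float(p)


def distortion_scan(abh: AbhMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-marker chi-square goodness of fit against the 1:2:1 expectation."""
    counts = abh.genotype_counts()
    n = counts[["n_A", "n_H", "n_B"]].to_numpy(dtype=float)
    tot = n.sum(axis=1)
    if (tot == 0).any():
        bad = abh.marker_ids[tot == 0][0]
        raise ValueError(f"marker {bad!r} has no non-missing calls")
    expected = np.stack([tot / 4.0, tot / 2.0, tot / 4.0], axis=1)
    chi2 = ((n - expected) ** 2 / expected).sum(axis=1)
    p = stats.chi2.sf(chi2, df=2)
    out = pd.DataFrame(
        {
            "marker": abh.marker_ids,
            "chromosome": abh.chromosome if abh.has_map else pd.NA,
            "cM": abh.position_cm if abh.has_map else np.nan,
            "n_A": n[:, 0].astype(int),
            "n_H": n[:, 1].astype(int),
            "n_B": n[:, 2].astype(int),
            "chi2": chi2,
            "p": p,
            "neglog10p": -np.log10(np.clip(p, 1e-300, None)),
            "significant_05": p < alpha,
        }
    )
    return out


def allele_frequency_profile(abh: AbhMatrix) -> pd.DataFrame:
    """Per-marker frequencies of A, H, B and missing over all calls."""
    n = abh.n_genotypes
    out = pd.DataFrame(
        {
            "marker": abh.marker_ids,
            "chromosome": abh.chromosome if abh.has_map else pd.NA,
            "cM": abh.position_cm if abh.has_map else np.nan,
            "freq_A": (abh.calls == CODE_A).sum(axis=0) / n,
            "freq_H": (abh.calls == CODE_H).sum(axis=0) / n,
            "freq_B": (abh.calls == CODE_B).sum(axis=0) / n,
            "freq_missing": (abh.calls == CODE_MISSING).sum(axis=0) / n,
        }
    )
    if abh.has_map:
        out = out.sort_values(["chromosome", "cM"], kind="stable").reset_index(drop=True)
    return out


# ----------------------------------------------------------------------
# Multivalent screen


def multivalent_screen(
    abh: AbhMatrix, flag_threshold: float = 0.5
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Maximum |marker correlation| for every pair of distinct chromosomes.

    Markers on the same chromosome are excluded (linkage is expected there).
    Chromosome pairs whose maximum absolute inter-chromosome marker
    correlation exceeds ``flag_threshold`` are returned as flags — the
    signature of chromosomes forced to co-segregate in a multivalent.
    """
    if not abh.has_map:
        raise ValueError("multivalent screen requires a map assignment")
    r = np.abs(pairwise_complete_correlation(abh.cd_matrix()))
    chroms = list(dict.fromkeys(abh.chromosome))
    mat = pd.DataFrame(np.nan, index=chroms, columns=chroms, dtype=float)
    flags: list[tuple[str, str]] = []
    for a_i, ca in enumerate(chroms):
        ia = np.nonzero(abh.chromosome == ca)[0]
        for cb in chroms[a_i + 1 :]:
            ib = np.nonzero(abh.chromosome == cb)[0]
            sub = r[np.ix_(ia, ib)]
            val = np.nanmax(sub) if np.isfinite(sub).any() else np.nan
            mat.loc[ca, cb] = mat.loc[cb, ca] = val
            if np.isfinite(val) and val > flag_threshold:
                flags.append((ca, cb))
    return mat, flags


# ----------------------------------------------------------------------
# Duplicate genotypes


def find_duplicate_genotypes(
    abh: AbhMatrix, min_identity: float = 0.99
) -> list[tuple[str, str]]:
    """Pairs of genotypes identical over at least ``min_identity`` of shared calls."""
    pairs: list[tuple[str, str]] = []
    calls = abh.calls
    ok = calls != CODE_MISSING
    for i in range(abh.n_genotypes):
        for j in range(i + 1, abh.n_genotypes):
            shared = ok[i] & ok[j]
            n = int(shared.sum())
            if n == 0:
                continue
            same = int((calls[i, shared] == calls[j, shared]).sum())
            if same / n >= min_identity:
                pairs.append((abh.genotype_ids[i], abh.genotype_ids[j]))
    return pairs


# ----------------------------------------------------------------------
# Helper for exercising the encode path


def raw_from_abh(
    abh: AbhMatrix, allele1: str = "G", allele2: str = "T"
) -> RawGenotypeMatrix:
    """Expand an ABH matrix into two-letter raw calls with homozygous parents."""
    lookup = {
        CODE_A: allele1 * 2,
        CODE_H: allele1 + allele2,
        CODE_B: allele2 * 2,
        CODE_MISSING: "NA",
    }
    calls = np.vectorize(lookup.get, otypes=[object])(abh.calls)
    m = abh.n_markers
    return RawGenotypeMatrix(
        calls=calls,
        genotype_ids=abh.genotype_ids,
        marker_ids=abh.marker_ids,
        parent1_calls=np.asarray([allele1 * 2] * m, dtype=object),
        parent2_calls=np.asarray([allele2 * 2] * m, dtype=object),
    )
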