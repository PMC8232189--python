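"""Genetic-map construction for an F2 intercross.

Two-point recombination fractions are estimated by maximum likelihood with
an EM step over the phase-ambiguous double-heterozygote class, linkage
groups are formed by single-linkage clustering on (rf, LOD) edges, marker
order within a group is found by a minimum-spanning-tree backbone refined
with 2-opt moves on the sum of adjacent recombination fractions, and
cumulative positions are assigned with the Kosambi map function
``d = 25 ln((1 + 2r) / (1 - 2r))`` cM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from .abh import AbhMatrix

__all__ = [
    "RecombinationEstimate",
    "estimate_rf",
    "pairwise_rf",
    "kosambi_cm",
    "kosambi_inverse",
    "group_markers",
    "order_markers",
    "build_map",
    "compare_maps",
]

_MIN_INFORMATIVE = 10


@dataclass(frozen=True)
class RecombinationEstimate:
    """Two-point recombination fraction with LOD support."""

    rf: float
    lod: float
    n_informative: int
    flagged: bool = False  # too few informative genotypes


# ----------------------------------------------------------------------
# Kosambi map function


def kosambi_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Map distance in cM for recombination fraction ``r`` (Kosambi)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a Kosambi map distance ``d`` in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    e = np.exp(d / 25.0)
    r = 0.5 * (e - 1.0) / (e + 1.0)
    return float(r) if r.ndim == 0 else r


# ----------------------------------------------------------------------
# Two-point recombination fraction

# expected recombinant gametes contributed by each unambiguous joint
# genotype cell (a, b) with a, b counting B alleles at the two loci
_REC_WEIGHT = np.array(
    [
        [0.0, 1.0, 2.0],
        [1.0, np.nan, 1.0],  # (1, 1) is the phase-ambiguous class
        [2.0, 1.0, 0.0],
    ]
)


def _cell_counts(ci: np.ndarray, cj: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over genotypes non-missing at both markers."""
    ok = (ci >= 0) & (cj >= 0)
    counts = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            counts[a, b] = np.sum((ci == a) & (cj == b) & ok)
    return counts


def _em_rf(counts: np.ndarray, n_iter: int = 200, tol: float = 1e-10) -> float:
    n = counts.sum()
    if n == 0:
        return 0.5
    fixed_rec = float(np.nansum(counts * _REC_WEIGHT))
    n_hh = counts[1, 1]
    r = 0.25
    for _ in range(n_iter):
        # E-step: expected recombinant gametes in the double-het class
        denom = (1.0 - r) ** 2 + r**2
        e_hh = n_hh * (2.0 * r**2 / denom) if denom > 0 else 0.0
        r_new = (fixed_rec + e_hh) / (2.0 * n)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return float(min(r, 0.5))


def _cell_loglik(counts: np.ndarray, r: float) -> float:
    pp = (1.0 - r) / 2.0
    pr = r / 2.0
    probs = np.array(
        [
            [pp**2, 2 * pp * pr, pr**2],
            [2 * pp * pr, 2 * (pp**2 + pr**2), 2 * pp * pr],
            [pr**2, 2 * pp * pr, pp**2],
        ]
    )
    with np.errstate(divide="ignore"):
        logp = np.log(np.clip(probs, 1e-300, None))
    return float((counts * logp).sum())


def estimate_rf(ci: np.ndarray, cj: np.ndarray) -> RecombinationEstimate:
    """ML recombination fraction between two codominant F2 marker columns.

    Columns are int8 ABH codes (0/1/2, -1 missing).  The estimate uses EM
    over the phase-ambiguous double-heterozygote class; the LOD score is the
    base-10 likelihood ratio against free recombination (r = 0.5).
    Estimates based on fewer than 10 informative genotypes are flagged.
    """
    counts = _cell_counts(np.asarray(ci), np.asarray(cj))
    n = int(counts.sum())
    if n < 2:
        raise ValueError("need at least two genotypes non-missing at both markers")
    r = _em_rf(counts)
    lod = (_cell_loglik(counts, r) - _cell_loglik(counts, 0.5)) / np.log(10.0)
    return RecombinationEstimate(
        rf=r, lod=max(lod, 0.0), n_informative=n, flagged=n < _MIN_INFORMATIVE
    )


def pairwise_rf(abh: AbhMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Recombination-fraction and LOD matrices for all marker pairs.

    Vectorized EM over all pairs at once; diagonal rf is 0 with LOD 0.
    """
    calls = abh.calls
    m = abh.n_markers
    ind = [(calls == a).astype(float) for a in range(3)]
    counts = {(a, b): ind[a].T @ ind[b] for a in range(3) for b in range(3)}
    n = sum(counts.values())
    fixed = (
        counts[0, 1]
        + counts[1, 0]
        + counts[1, 2]
        + counts[2, 1]
        + 2.0 * (counts[0, 2] + counts[2, 0])
    )
    n_hh = counts[1, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.full((m, m), 0.25)
        for _ in range(200):
            denom = (1.0 - r) ** 2 + r**2
            e_hh = n_hh * (2.0 * r**2 / denom)
            r_new = np.where(n > 0, (fixed + e_hh) / (2.0 * np.maximum(n, 1)), 0.5)
            if np.nanmax(np.abs(r_new - r)) < 1e-10:
                r = r_new
                break
            r = r_new
        r = np.clip(r, 0.0, 0.5)

        def loglik(rr: np.ndarray) -> np.ndarray:
            pp = (1.0 - rr) / 2.0
            pr = rr / 2.0
            cell_p = {
                (0, 0): pp**2,
                (0, 1): 2 * pp * pr,
                (0, 2): pr**2,
                (1, 0): 2 * pp * pr,
                (1, 1): 2 * (pp**2 + pr**2),
                (1, 2): 2 * pp * pr,
                (2, 0): pr**2,
                (2, 1): 2 * pp * pr,
                (2, 2): pp**2,
            }
            ll = np.zeros_like(rr)
            for key, p in cell_p.items():
                ll += counts[key] * np.log(np.clip(p, 1e-300, None))
            return ll

        lod = (loglik(r) - loglik(np.full_like(r, 0.5))) / np.log(10.0)
    lod = np.maximum(np.nan_to_num(lod, nan=0.0), 0.0)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, 0.0)
    return r, lod


# ----------------------------------------------------------------------
# Grouping and ordering


def group_markers(
    rf: np.ndarray,
    lod: np.ndarray,
    rf_max: float = 0.35,
    lod_min: float = 6.0,
) -> list[list[int]]:
    """Single-linkage clustering on edges with rf <= rf_max and LOD >= lod_min.

    Returns linkage groups as lists of marker indices, largest group first
    (ties by smallest member index).
    """
    m = rf.shape[0]
    adj = (rf <= rf_max) & (lod >= lod_min)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [list(np.nonzero(labels == k)[0]) for k in range(n_comp)]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def _path_from_mst(dist: np.ndarray) -> list[int]:
    """Initial marker order: DFS preorder of the MST from a diameter endpoint."""
    m = dist.shape[0]
    mst = minimum_spanning_tree(csr_matrix(dist + 1e-9))  # offset keeps 0-rf edges
    mst = mst + mst.T
    adj: list[list[int]] = [[] for _ in range(m)]
    rows, cols = mst.nonzero()
    for i, j in zip(rows, cols):
        adj[i].append(int(j))

    def farthest(start: int) -> int:
        seen = {start}
        stack = [start]
        last = start
        while stack:
            node = stack.pop()
            last = node
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return last

    start = farthest(0)
    order: list[int] = []
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        order.append(node)
        for nb in sorted(adj[node], key=lambda j: -dist[node, j]):
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return order


def _greedy_path(dist: np.ndarray, start: int) -> list[int]:
    m = dist.shape[0]
    visited = np.zeros(m, dtype=bool)
    order = [start]
    visited[start] = True
    while len(order) < m:
        d = dist[order[-1]].copy()
        d[visited] = np.inf
        nxt = int(np.argmin(d))
        order.append(nxt)
        visited[nxt] = True
    return order


def _path_cost(order: list[int], dist: np.ndarray) -> float:
    idx = np.asarray(order)
    return float(dist[idx[:-1], idx[1:]].sum())


def _two_opt(order: list[int], dist: np.ndarray, max_rounds: int = 200) -> list[int]:
    """2-opt refinement of an open path minimizing sum of adjacent distances."""
    order = list(order)
    m = len(order)
    improved = True
    rounds = 0
    while improved and rounds < max_rounds:
        improved = False
        rounds += 1
        for i in range(m - 1):
            a = order[i - 1] if i > 0 else None
            for j in range(i + 1, m):
                b = order[j + 1] if j + 1 < m else None
                old = 0.0
                new = 0.0
                if a is not None:
                    old += dist[a, order[i]]
                    new += dist[a, order[j]]
                if b is not None:
                    old += dist[order[j], b]
                    new += dist[order[i], b]
                if new < old - 1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
    return order


def order_markers(
    group: list[int], rf: np.ndarray
) -> tuple[list[int], np.ndarray]:
    """Order a linkage group and assign cumulative Kosambi cM positions.

    The order minimizes the sum of adjacent recombination fractions via an
    MST-backbone initial path plus greedy starts, each refined by 2-opt; the
    chromosome orientation is fixed by anchoring to the group's first marker
    (it is placed in the first half of the order).
    """
    if len(group) < 2:
        return list(group), np.zeros(len(group))
    sub = rf[np.ix_(group, group)].astype(float)
    m = len(group)
    candidates = [_path_from_mst(sub), _greedy_path(sub, 0), _greedy_path(sub, m - 1)]
    best = None
    best_cost = np.inf
    for cand in candidates:
        refined = _two_opt(cand, sub)
        cost = _path_cost(refined, sub)
        if cost < best_cost - 1e-15:
            best_cost = cost
            best = refined
    assert best is not None
    # orientation anchor: first input marker sits in the first half
    anchor_pos = best.index(0)
    if anchor_pos > (m - 1) - anchor_pos:
        best = best[::-1]
    adj = sub[np.asarray(best[:-1]), np.asarray(best[1:])]
    cm = np.concatenate([[0.0], np.cumsum(kosambi_cm(np.minimum(adj, 0.499999)))])
    return [group[i] for i in best], cm


def build_map(
    abh: AbhMatrix,
    rf_max: float = 0.35,
    lod_min: float = 6.0,
) -> pd.DataFrame:
    """Full map construction: pairwise rf, grouping, ordering, positions.

    Returns a table with columns ``marker, group, order, cM`` (groups named
    ``LG1``... by decreasing size).
    """
    rf, lod = pairwise_rf(abh)
    groups = group_markers(rf, lod, rf_max=rf_max, lod_min=lod_min)
    rows = []
    for k, grp in enumerate(groups, start=1):
        order, cm = order_markers(grp, rf)
        for pos, (idx, c) in enumerate(zip(order, cm)):
            rows.append(
                {
                    "marker": abh.marker_ids[idx],
                    "group": f"LG{k}",
                    "order": pos,
                    "cM": float(c),
                }
            )
    return pd.DataFrame(rows)


def compare_maps(
    constructed: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Concordance report of a constructed map against a reference map.

    ``constructed`` has columns ``marker, group, cM`` (as from
    :func:`build_map`); ``reference`` has ``marker, chromosome, cM``.  For
    every linkage group the report gives the number of shared markers, the
    majority reference chromosome with its purity, the absolute Spearman
    rank correlation of marker order over shared markers (1.0 up to
    whole-chromosome reversal), and the map-length ratio.
    """
    merged = constructed.merge(
        reference, on="marker", suffixes=("", "_ref"), how="inner"
    )
    rows = []
    for name, grp in merged.groupby("group"):
        top = grp["chromosome"].mode().iloc[0] if "chromosome" in grp else None
        on_top = grp[grp["chromosome"] == top] if top is not None else grp
        if len(on_top) > 2:
            rho = on_top["cM"].rank().corr(on_top["cM_ref"].rank(), method="pearson")
        else:
            rho = np.nan
        span = grp["cM"].max() - grp["cM"].min()
        span_ref = on_top["cM_ref"].max() - on_top["cM_ref"].min()
        rows.append(
            {
                "group": name,
                "n_shared": len(grp),
                "ref_chromosome": top,
                "purity": len(on_top) / len(grp),
                "order_correlation": abs(rho) if np.isfinite(rho) else np.nan,
                "length_ratio": span / span_ref if span_ref > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
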