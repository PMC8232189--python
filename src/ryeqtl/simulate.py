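"""Simulated meiosis and F2/F3 population generation with ground truth.

Meiosis follows a Haldane (no-interference) crossover process: crossover
counts per chromosome are Poisson with mean length/100 and positions are
uniform.  For the marker loci — the only observables — this is realized
exactly by its marginal form: the parental origin flips between adjacent
markers with independent probability ``(1 - exp(-2 d / 100)) / 2`` for an
inter-marker distance of ``d`` cM.

Gametophytic selection is implemented by rejection sampling (inviable
gametes are discarded and redrawn), mirroring the biological filtering:

* pollen-side *Z* selection: pollen carrying the B allele at *Z* is
  discarded; egg gametes are never filtered;
* multivalent co-segregation: the three ring chromosomes disjoin whole
  (no crossover) and a gamete is viable only when all three derive from
  the same parental species.

Phenotypes are generated under the randomized-complete-block trial model
``y_ijkl = mu + g_i + l_j + r_jk + (gl)_ij + e_ijkl`` with independent
normal draws for every random term and an optional clip to the trait's
bounded score scale (recorded in the truth record).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abh import CODE_MISSING, AbhMatrix
from .genome import (
    FERTILITY_DESIGN,
    PERENNIALITY_DESIGN,
    GenomeSpec,
    QtlEffectSpec,
    SelectionSpec,
    TrialDesign,
    default_fertility_qtls,
    default_genome,
    default_perenniality_qtls,
    default_selection,
)

__all__ = [
    "simulate_gamete",
    "simulate_f2",
    "simulate_f3_selfing",
    "simulate_phenotypes",
    "simulate_study",
    "genome_from_abh",
    "add_missing_calls",
    "add_duplicate_markers",
    "PhenotypeResult",
    "SimulatedStudy",
]


# ----------------------------------------------------------------------
# Gamete machinery


def _flip_probabilities(genome: GenomeSpec) -> list[np.ndarray]:
    """Per-chromosome inter-marker origin-flip probabilities (Haldane)."""
    out = []
    for name, _ in genome.chromosomes:
        d = np.diff(genome.marker_positions[name])
        out.append(0.5 * (1.0 - np.exp(-2.0 * d / 100.0)))
    return out


def _free_origins(n: int, genome: GenomeSpec, rng: np.random.Generator) -> np.ndarray:
    """Parental-origin vectors (n x total markers) for unselected gametes."""
    blocks = []
    for (name, _), p in zip(genome.chromosomes, _flip_probabilities(genome)):
        m = len(genome.marker_positions[name])
        start = rng.integers(0, 2, size=(n, 1))
        if m > 1:
            flips = rng.random((n, m - 1)) < p
            cum = np.cumsum(flips, axis=1)
            origins = (start + np.concatenate([np.zeros((n, 1), dtype=int), cum], axis=1)) % 2
        else:
            origins = start
        blocks.append(origins.astype(np.int8))
    return np.concatenate(blocks, axis=1)


def _apply_multivalent(
    origins: np.ndarray,
    genome: GenomeSpec,
    chroms: frozenset[str],
    rng: np.random.Generator,
) -> None:
    """Overwrite multivalent chromosomes with viable whole-chromosome origins.

    Each ring chromosome disjoins whole; rejection keeps only gametes whose
    three multivalent chromosomes share one parental origin.
    """
    if not chroms:
        return
    names = [c for c in genome.chromosome_names if c in chroms]
    n = origins.shape[0]
    bits = rng.integers(0, 2, size=(n, len(names)), dtype=np.int8)
    bad = ~np.all(bits == bits[:, :1], axis=1)
    while bad.any():
        bits[bad] = rng.integers(0, 2, size=(int(bad.sum()), len(names)), dtype=np.int8)
        bad = ~np.all(bits == bits[:, :1], axis=1)
    slices = genome.chrom_slices()
    for j, name in enumerate(names):
        origins[:, slices[name]] = bits[:, j][:, None]


def _gamete_alleles(
    phase: np.ndarray,
    parent_idx: np.ndarray,
    genome: GenomeSpec,
    rng: np.random.Generator,
    selection: SelectionSpec | None,
    pollen: bool,
) -> np.ndarray:
    """Allele vectors of gametes drawn from phased parents.

    ``phase`` has shape (n_parents, 2, M) with parental-origin alleles 0/1;
    one gamete is produced per entry of ``parent_idx``.  Pollen gametes are
    Z-filtered (redrawn) when the selection spec defines a Z locus.
    """
    n = len(parent_idx)
    marker_ix = np.arange(phase.shape[2])

    def draw(k: int, idx: np.ndarray) -> np.ndarray:
        origins = _free_origins(k, genome, rng)
        if selection is not None:
            _apply_multivalent(origins, genome, selection.multivalent_chromosomes, rng)
        return phase[idx[:, None], origins, marker_ix[None, :]]

    alleles = draw(n, parent_idx)
    if pollen and selection is not None and selection.z_locus is not None:
        z = genome.locus_index(selection.z_locus)
        # parents without any A allele at Z can never produce compatible pollen
        if (phase[parent_idx, :, z] == 1).all(axis=1).any():
            raise ValueError("parent homozygous B at the Z locus cannot produce pollen")
        bad = alleles[:, z] == 1
        while bad.any():
            idx = parent_idx[bad]
            alleles[bad] = draw(int(bad.sum()), idx)
            bad_new = np.zeros_like(bad)
            bad_new[bad] = alleles[bad, z] == 1
            bad = bad_new
    return alleles.astype(np.int8)


def simulate_gamete(
    parent: np.ndarray, genome: GenomeSpec, rng: np.random.Generator
) -> np.ndarray:
    """One gamete (allele vector over all markers) from a phased diplotype.

    ``parent`` must be phased: shape ``(2, M)`` with haplotype alleles 0/1
    over all marker positions of ``genome``.
    """
    parent = np.asarray(parent)
    if parent.ndim != 2 or parent.shape[0] != 2 or parent.shape[1] != genome.n_markers:
        raise ValueError(
            "parent must be a phased diplotype of shape (2, n_markers); "
            f"got shape {parent.shape}"
        )
    if not np.isin(parent, (0, 1)).all():
        raise ValueError("phased haplotype alleles must be 0 or 1")
    return _gamete_alleles(
        parent[None, :, :], np.zeros(1, dtype=int), genome, rng, None, pollen=False
    )[0]


# ----------------------------------------------------------------------
# Populations


def simulate_f2(
    genome: GenomeSpec,
    n_genotypes: int,
    selection: SelectionSpec | None = None,
    rng: np.random.Generator | None = None,
) -> AbhMatrix:
    """F2 population from selfing an F1 that is heterozygous at every marker.

    Each F2 individual is the union of an (unfiltered) egg gamete and a
    pollen gamete; pollen carrying the B allele at the Z locus is discarded
    and redrawn when Z selection is configured.  The returned matrix carries
    the map annotation and the phased haplotypes of every individual.
    """
    if n_genotypes < 1:
        raise ValueError("n_genotypes must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    if selection is not None:
        selection.validate_on(genome)
    m = genome.n_markers
    f1_phase = np.stack([np.zeros(m, dtype=np.int8), np.ones(m, dtype=np.int8)])[None]
    parent_idx = np.zeros(n_genotypes, dtype=int)
    eggs = _gamete_alleles(f1_phase, parent_idx, genome, rng, selection, pollen=False)
    pollen = _gamete_alleles(f1_phase, parent_idx, genome, rng, selection, pollen=True)
    calls = (eggs + pollen).astype(np.int8)  # count of B alleles == ABH code
    width = max(4, len(str(n_genotypes)))
    ids = np.asarray([f"F2_{i:0{width}d}" for i in range(1, n_genotypes + 1)], dtype=object)
    return AbhMatrix(
        calls=calls,
        genotype_ids=ids,
        marker_ids=genome.marker_ids(),
        chromosome=genome.marker_chromosomes(),
        position_cm=genome.marker_cm(),
        phase=np.stack([eggs, pollen], axis=1),
    )


def genome_from_abh(abh: AbhMatrix) -> GenomeSpec:
    """Reconstruct a genome spec from a mapped ABH matrix."""
    if not abh.has_map:
        raise ValueError("matrix has no chromosome/position annotation")
    names: list[str] = []
    for c in abh.chromosome:  # preserve first-appearance order
        if c not in names:
            names.append(c)
    positions = {}
    chroms = []
    for name in names:
        pos = abh.position_cm[abh.chromosome == name]
        positions[name] = np.asarray(pos, dtype=float)
        chroms.append((name, float(pos.max()) if len(pos) else 0.0))
    return GenomeSpec(chromosomes=tuple(chroms), marker_positions=positions)


def simulate_f3_selfing(
    f2: AbhMatrix,
    selection: SelectionSpec,
    rng: np.random.Generator | None = None,
    family_size: int = 1,
) -> AbhMatrix:
    """Pooled F3 generation from selfing every selfable F2 plant.

    Selfability is stigma-side at *S5* (dominant self-fertility A allele:
    BB plants set no selfed seed).  Selfable plants contribute equal-sized
    families of ``family_size`` offspring, each the union of an unfiltered
    egg and a Z-filtered pollen gamete from the same parent.
    """
    if selection.s5_locus is None:
        raise ValueError("selection must define the S5 locus for selfing")
    if f2.phase is None:
        raise ValueError("F2 matrix must carry phased haplotypes (simulated truth)")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    genome = genome_from_abh(f2)
    selection.validate_on(genome)
    s5 = genome.locus_index(selection.s5_locus)
    selfable = f2.calls[:, s5] < 2  # at least one A allele at S5
    if selection.z_locus is not None:
        z = genome.locus_index(selection.z_locus)
        selfable &= f2.calls[:, z] < 2  # BB at Z has no compatible pollen
    parent_rows = np.nonzero(selfable)[0]
    if parent_rows.size == 0:
        return AbhMatrix(
            calls=np.empty((0, f2.n_markers), dtype=np.int8),
            genotype_ids=np.empty(0, dtype=object),
            marker_ids=f2.marker_ids,
            chromosome=f2.chromosome,
            position_cm=f2.position_cm,
        )
    parent_idx = np.repeat(parent_rows, family_size)
    eggs = _gamete_alleles(f2.phase, parent_idx, genome, rng, selection, pollen=False)
    pollen = _gamete_alleles(f2.phase, parent_idx, genome, rng, selection, pollen=True)
    calls = (eggs + pollen).astype(np.int8)
    ids = np.asarray(
        [
            f"F3_{f2.genotype_ids[p]}_{k + 1}"
            for p in parent_rows
            for k in range(family_size)
        ],
        dtype=object,
    )
    return AbhMatrix(
        calls=calls,
        genotype_ids=ids,
        marker_ids=f2.marker_ids,
        chromosome=f2.chromosome,
        position_cm=f2.position_cm,
        phase=np.stack([eggs, pollen], axis=1),
    )


# ----------------------------------------------------------------------
# Phenotypes


@dataclass
class PhenotypeResult:
    """Plot-level phenotype table plus the generating ground truth."""

    plots: pd.DataFrame
    truth: dict


def _qtl_marker_index(abh: AbhMatrix, qtl: QtlEffectSpec) -> int:
    if not abh.has_map:
        raise ValueError("genotype matrix has no map annotation")
    chrom, cm = qtl.locus
    hits = np.nonzero((abh.chromosome == chrom) & np.isclose(abh.position_cm, cm))[0]
    if hits.size == 0:
        raise ValueError(f"QTL locus {chrom}:{cm} cM has no genotyped marker")
    return int(hits[0])


def simulate_phenotypes(
    f2: AbhMatrix,
    qtls: Sequence[QtlEffectSpec],
    design: TrialDesign,
    rng: np.random.Generator | None = None,
    trait: str = "trait",
    mu: float = 0.0,
) -> PhenotypeResult:
    """Plot-level phenotypes for a genotyped population under a trial design.

    The genotype value is ``g_i = sum_q (cd_q x_cd + d_q x_d) + N(0,
    sigma2_g_residual)``; plot values add location, replicate-in-location,
    genotype-by-location and residual draws, and are optionally clipped to
    the trait bounds (the number of clipped plots is recorded in the truth).
    """
    rng = np.random.default_rng() if rng is None else rng
    n = f2.n_genotypes
    g = rng.normal(0.0, np.sqrt(design.sigma2_g_residual), size=n)
    for qtl in qtls:
        col = f2.calls[:, _qtl_marker_index(f2, qtl)]
        if (col == CODE_MISSING).any():
            raise ValueError(f"missing genotype calls at QTL marker for {qtl.trait}")
        x_cd = col.astype(float)
        x_d = (col == 1).astype(float)
        g = g + qtl.cd_effect * x_cd + qtl.d_effect * x_d
    L, R = design.n_locations, design.n_replicates
    loc = rng.normal(0.0, np.sqrt(design.sigma2_location), size=L)
    rep = rng.normal(0.0, np.sqrt(design.sigma2_replicate), size=(L, R))
    gxl = rng.normal(0.0, np.sqrt(design.sigma2_gxl), size=(n, L))
    err = rng.normal(0.0, np.sqrt(design.sigma2_error), size=(n, L, R))
    values = (
        mu
        + g[:, None, None]
        + loc[None, :, None]
        + rep[None, :, :]
        + gxl[:, :, None]
        + err
    )
    n_clipped = 0
    if design.trait_bounds is not None:
        lo, hi = design.trait_bounds
        n_clipped = int(((values < lo) | (values > hi)).sum())
        values = np.clip(values, lo, hi)
    rows = {
        "genotype": np.repeat(f2.genotype_ids, L * R),
        "location": np.tile(np.repeat([f"L{j + 1}" for j in range(L)], R), n),
        "replicate": np.tile([f"R{k + 1}" for k in range(R)], n * L),
        "trait": trait,
        "value": values.reshape(-1),
    }
    plots = pd.DataFrame(rows)
    truth = {
        "trait": trait,
        "mu": mu,
        "genotype_values": dict(zip(f2.genotype_ids, g)),
        "qtls": list(qtls),
        "design": design,
        "n_clipped": n_clipped,
    }
    return PhenotypeResult(plots=plots, truth=truth)


# ----------------------------------------------------------------------
# Whole-study generation


@dataclass
class SimulatedStudy:
    """A complete synthetic study: genotypes, plot phenotypes, ground truth."""

    abh: AbhMatrix
    phenotypes: pd.DataFrame
    truth: dict = field(default_factory=dict)


def simulate_study(
    genome: GenomeSpec | None = None,
    n_genotypes: int = 178,
    selection: SelectionSpec | None = None,
    traits: Mapping[str, tuple[Sequence[QtlEffectSpec], TrialDesign, float]] | None = None,
    seed: int = 0,
) -> SimulatedStudy:
    """Generate the default perennial-rye-scale synthetic study.

    ``traits`` maps a trait name to ``(qtls, design, mu)``; the default
    plants the perenniality and fertility QTL sets with their trial designs
    and incompatibility selection at *Z* (2R) and *S5* (5R).
    """
    genome = genome or default_genome()
    if selection is None:
        selection = default_selection(genome)
    if traits is None:
        traits = {
            "perenniality": (default_perenniality_qtls(genome), PERENNIALITY_DESIGN, 0.0),
            "fertility": (default_fertility_qtls(genome), FERTILITY_DESIGN, 85.0),
        }
    rng = np.random.default_rng(seed)
    abh = simulate_f2(genome, n_genotypes, selection=selection, rng=rng)
    pheno_frames = []
    trait_truth = {}
    for name, (qtls, design, mu) in traits.items():
        res = simulate_phenotypes(abh, qtls, design, rng=rng, trait=name, mu=mu)
        pheno_frames.append(res.plots)
        trait_truth[name] = res.truth
    counts = abh.genotype_counts()
    n = abh.n_genotypes
    truth = {
        "seed": seed,
        "n_genotypes": n_genotypes,
        "selection": selection,
        "traits": trait_truth,
        "realized_frequencies": {
            "A": float(counts["n_A"].mean() / n),
            "H": float(counts["n_H"].mean() / n),
            "B": float(counts["n_B"].mean() / n),
        },
    }
    phenotypes = (
        pd.concat(pheno_frames, ignore_index=True)
        if pheno_frames
        else pd.DataFrame(columns=["genotype", "location", "replicate", "trait", "value"])
    )
    return SimulatedStudy(abh=abh, phenotypes=phenotypes, truth=truth)


# ----------------------------------------------------------------------
# Perturbation helpers for QC exercises


def add_missing_calls(
    abh: AbhMatrix, rate: float, rng: np.random.Generator
) -> AbhMatrix:
    """Set a random fraction of calls to missing (missing-at-random)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    out = abh.copy()
    mask = rng.random(out.calls.shape) < rate
    out.calls[mask] = CODE_MISSING
    return out


def add_duplicate_markers(
    abh: AbhMatrix, n_copies: int, rng: np.random.Generator, suffix: str = "dup"
) -> AbhMatrix:
    """Append exact copies of randomly chosen markers (planted redundancy)."""
    if n_copies < 1:
        return abh.copy()
    src = rng.integers(0, abh.n_markers, size=n_copies)
    calls = np.concatenate([abh.calls, abh.calls[:, src]], axis=1)
    ids = np.concatenate(
        [
            abh.marker_ids,
            [f"{abh.marker_ids[j]}_{suffix}{k}" for k, j in enumerate(src)],
        ]
    )
    chrom = pos = None
    if abh.has_map:
        chrom = np.concatenate([abh.chromosome, abh.chromosome[src]])
        pos = np.concatenate([abh.position_cm, abh.position_cm[src]])
    return AbhMatrix(
        calls=calls.astype(np.int8),
        genotype_ids=abh.genotype_ids,
        marker_ids=np.asarray(ids, dtype=object),
        chromosome=chrom,
        position_cm=pos,
    )
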