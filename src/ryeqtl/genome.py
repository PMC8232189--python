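"""Genome, QTL, selection and trial-design specifications.

The default preset mirrors the scale of the perennial-rye F2 study this
package emulates: seven chromosomes (1R-7R) of 120 cM carrying 113 evenly
spaced markers each (791 total), 178 F2 genotypes, two locations with two
clonal replicates, a 0-9 perenniality score and a 0-100 % fertility score,
pollen-side gametophytic selection at the *Z* locus (2R) and stigma-side
selection at the *S5* locus (5R).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Locus = tuple[str, float]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome lengths (cM) and ordered marker positions per chromosome."""

    chromosomes: tuple[tuple[str, float], ...]
    marker_positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length < 0:
                raise ValueError(f"chromosome {name}: negative length")
            pos = np.asarray(self.marker_positions[name], dtype=float)
            if pos.size == 0:
                raise ValueError(f"chromosome {name}: no markers")
            if (np.diff(pos) < 0).any():
                raise ValueError(f"chromosome {name}: positions not sorted")
            if pos[0] < 0 or pos[-1] > length:
                raise ValueError(f"chromosome {name}: positions outside [0, length]")
            object.__setattr__(
                self,
                "marker_positions",
                {**self.marker_positions, name: pos},
            )

    # ------------------------------------------------------------------
    @property
    def chromosome_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.marker_positions.values())

    def length_of(self, chrom: str) -> float:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def marker_ids(self) -> np.ndarray:
        ids: list[str] = []
        for name, _ in self.chromosomes:
            ids.extend(
                f"{name}_{i:03d}" for i in range(len(self.marker_positions[name]))
            )
        return np.asarray(ids, dtype=object)

    def marker_chromosomes(self) -> np.ndarray:
        out: list[str] = []
        for name, _ in self.chromosomes:
            out.extend([name] * len(self.marker_positions[name]))
        return np.asarray(out, dtype=object)

    def marker_cm(self) -> np.ndarray:
        return np.concatenate(
            [self.marker_positions[name] for name, _ in self.chromosomes]
        )

    def chrom_slices(self) -> dict[str, slice]:
        """Column slice of each chromosome in the concatenated marker order."""
        out: dict[str, slice] = {}
        start = 0
        for name, _ in self.chromosomes:
            m = len(self.marker_positions[name])
            out[name] = slice(start, start + m)
            start += m
        return out

    def locus_index(self, locus: Locus) -> int:
        """Global marker index of a locus; the locus must sit on a marker."""
        chrom, cm = locus
        if chrom not in self.marker_positions:
            raise ValueError(f"locus chromosome {chrom!r} is not on the genome")
        pos = self.marker_positions[chrom]
        hits = np.nonzero(np.isclose(pos, cm, atol=1e-9))[0]
        if hits.size == 0:
            raise ValueError(
                f"no marker at {chrom}:{cm} cM; use snap_to_marker() first"
            )
        return self.chrom_slices()[chrom].start + int(hits[0])

    def snap_to_marker(self, chrom: str, cm: float) -> Locus:
        """Nearest marker position on ``chrom`` to the requested cM."""
        if chrom not in self.marker_positions:
            raise ValueError(f"unknown chromosome {chrom!r}")
        pos = self.marker_positions[chrom]
        return chrom, float(pos[np.argmin(np.abs(pos - cm))])


def uniform_genome(
    chromosomes: tuple[tuple[str, float], ...],
    markers_per_chromosome: int,
) -> GenomeSpec:
    """Genome with evenly spaced markers spanning each chromosome."""
    positions = {
        name: np.linspace(0.0, length, markers_per_chromosome)
        if markers_per_chromosome > 1
        else np.array([0.0])
        for name, length in chromosomes
    }
    return GenomeSpec(chromosomes=chromosomes, marker_positions=positions)


def default_genome() -> GenomeSpec:
    """Seven rye chromosomes (1R-7R), 120 cM, 113 markers each (791 total)."""
    return uniform_genome(
        tuple((f"{i}R", 120.0) for i in range(1, 8)), markers_per_chromosome=113
    )


@dataclass(frozen=True)
class QtlEffectSpec:
    """A planted QTL: additive (per B-allele copy) and dominance effects."""

    trait: str
    locus: Locus
    cd_effect: float
    d_effect: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cd_effect) and np.isfinite(self.d_effect)):
            raise ValueError("QTL effects must be finite")


@dataclass(frozen=True)
class SelectionSpec:
    """Gametophytic-selection and multivalent-co-segregation settings.

    ``z_locus`` acts on the pollen side only: a pollen gamete carrying the
    B allele at *Z* cannot fertilize.  ``s5_locus`` acts on the stigma side
    during selfing: only plants with at least one A (self-fertility) allele
    at *S5* set selfed seed.  ``multivalent_chromosomes`` forces the named
    chromosomes to co-segregate as a ring multivalent (whole-chromosome
    disjunction; a gamete is viable only when all of them derive from the
    same parental species).
    """

    z_locus: Locus | None = None
    s5_locus: Locus | None = None
    multivalent_chromosomes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        mv = frozenset(self.multivalent_chromosomes)
        object.__setattr__(self, "multivalent_chromosomes", mv)
        if mv and len(mv) != 3:
            raise ValueError("multivalent chromosome set must be empty or of size 3")

    def validate_on(self, genome: GenomeSpec) -> None:
        for locus in (self.z_locus, self.s5_locus):
            if locus is not None:
                genome.locus_index(locus)
        unknown = self.multivalent_chromosomes - set(genome.chromosome_names)
        if unknown:
            raise ValueError(f"multivalent chromosomes not on genome: {sorted(unknown)}")


@dataclass(frozen=True)
class TrialDesign:
    """Field-trial layout and variance components for phenotype simulation.

    Variances are on the trait scale: ``sigma2_location`` (location main
    effect), ``sigma2_replicate`` (replicate nested in location),
    ``sigma2_gxl`` (genotype-by-location interaction), ``sigma2_error``
    (plot residual) and ``sigma2_g_residual`` (polygenic genetic background
    not attached to any simulated marker).
    """

    n_locations: int = 2
    n_replicates: int = 2
    sigma2_location: float = 0.0
    sigma2_replicate: float = 0.0
    sigma2_gxl: float = 0.0
    sigma2_error: float = 1.0
    sigma2_g_residual: float = 0.0
    trait_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_locations < 1 or self.n_replicates < 1:
            raise ValueError("need at least one location and one replicate")
        for name in (
            "sigma2_location",
            "sigma2_replicate",
            "sigma2_gxl",
            "sigma2_error",
            "sigma2_g_residual",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.trait_bounds is not None and self.trait_bounds[0] >= self.trait_bounds[1]:
            raise ValueError("trait bounds must be an increasing pair")


# ----------------------------------------------------------------------
# Default study presets (perennial-rye scale)

#: Table-style variance components for the perenniality score (0-9),
#: assessed at two locations with two clonal replicates.
PERENNIALITY_DESIGN = TrialDesign(
    n_locations=2,
    n_replicates=2,
    sigma2_location=0.22,
    sigma2_replicate=0.08,
    sigma2_gxl=1.18,
    sigma2_error=1.39,
    sigma2_g_residual=0.97,
    trait_bounds=(0.0, 9.0),
)

#: Fertility (%) was scored at a single location with two replicates.
FERTILITY_DESIGN = TrialDesign(
    n_locations=1,
    n_replicates=2,
    sigma2_location=0.0,
    sigma2_replicate=2.6,
    sigma2_gxl=0.0,
    sigma2_error=94.9,
    sigma2_g_residual=113.0,
    trait_bounds=(0.0, 100.0),
)


def default_selection(genome: GenomeSpec | None = None) -> SelectionSpec:
    """*Z* on distal 2R (~115 cM) and *S5* on 5R (~42 cM), snapped to markers."""
    genome = genome or default_genome()
    return SelectionSpec(
        z_locus=genome.snap_to_marker("2R", 115.0),
        s5_locus=genome.snap_to_marker("5R", 42.0),
    )


def default_perenniality_qtls(genome: GenomeSpec | None = None) -> list[QtlEffectSpec]:
    """Five additive-to-dominant perenniality QTLs on 2R/3R/4R/5R/7R."""
    genome = genome or default_genome()
    specs = [
        ("2R", 121.0, -0.69, 1.32),
        ("3R", 71.1, 0.58, 0.34),
        ("4R", 72.0, 1.15, 0.07),
        ("5R", 77.0, 1.34, -0.04),
        ("7R", 0.6, 0.64, 1.61),
    ]
    return [
        QtlEffectSpec(
            trait="perenniality",
            locus=genome.snap_to_marker(chrom, cm),
            cd_effect=cd,
            d_effect=d,
        )
        for chrom, cm, cd, d in specs
    ]


def default_fertility_qtls(genome: GenomeSpec | None = None) -> list[QtlEffectSpec]:
    """A major *S5*-linked fertility locus on 5R plus minor loci on 1R/4R."""
    genome = genome or default_genome()
    specs = [
        ("1R", 63.2, -7.7, 8.1),
        ("4R", 78.2, -7.3, -7.2),
        ("5R", 41.7, -18.4, 14.9),
    ]
    return [
        QtlEffectSpec(
            trait="fertility",
            locus=genome.snap_to_marker(chrom, cm),
            cd_effect=cd,
            d_effect=d,
        )
        for chrom, cm, cd, d in specs
    ]
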