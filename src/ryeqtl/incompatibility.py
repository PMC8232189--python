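"""Closed-form gametophytic self-incompatibility and multivalent models.

Two loci govern selfing success in the perennial-rye cross modeled here.
Alleles are written A (from the self-fertile inbred annual parent) and B
(from the self-incompatible perennial parent):

* *Z* acts through the haploid pollen grain: only pollen carrying the A
  (self-fertility) allele at *Z* can fertilize in a selfing context.
* *S5* acts through the diploid stigma: the self-fertility allele is
  dominant, so a plant permits selfing iff it carries at least one A at
  *S5*.  Pollen is unrestricted at *S5*.

The multivalent model describes a ring of translocated chromosomes at
meiotic metaphase I.  Each homologous pair contributes exactly one
chromosome to a gamete, independently and equiprobably; a gamete is
functional only when every contributed chromosome derives from the same
parental species.  All ratios returned here are exact rationals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product

__all__ = [
    "LocusGenotype",
    "PollenHaplotype",
    "MultivalentModel",
    "GenotypeRatio",
    "pollen_compatible",
    "stigma_selfable",
    "expected_f2_ratio",
    "expected_f3_ratio_s5",
    "multivalent_viable_fraction",
]

_ALLELES = ("A", "B")
_LOCI = ("Z", "S5")


@dataclass(frozen=True)
class LocusGenotype:
    """Diploid genotype at one incompatibility locus (unordered allele pair)."""

    locus: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if self.locus not in _LOCI:
            raise ValueError(f"locus must be one of {_LOCI}, got {self.locus!r}")
        if len(self.alleles) != 2 or any(a not in _ALLELES for a in self.alleles):
            raise ValueError("alleles must be a pair from {A, B}")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def abh(self) -> str:
        """ABH call for this allele pair (AA -> A, AB -> H, BB -> B)."""
        return {("A", "A"): "A", ("A", "B"): "H", ("B", "B"): "B"}[self.alleles]


@dataclass(frozen=True)
class PollenHaplotype:
    """Haploid pollen genotype: one allele at *Z* and one at *S5*."""

    z: str
    s5: str

    def __post_init__(self) -> None:
        if self.z not in _ALLELES or self.s5 not in _ALLELES:
            raise ValueError("pollen alleles must be from {A, B}")


@dataclass(frozen=True)
class MultivalentModel:
    """Ring multivalent of ``n_pairs`` homologous chromosome pairs."""

    n_pairs: int = 3

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass(frozen=True)
class GenotypeRatio:
    """Exact A:H:B genotype ratio at a biallelic locus."""

    a: Fraction
    h: Fraction
    b: Fraction

    def normalized(self) -> tuple[Fraction, Fraction, Fraction]:
        total = self.a + self.h + self.b
        return self.a / total, self.h / total, self.b / total

    def as_integer_ratio(self) -> tuple[int, int, int]:
        """Smallest integer triple with the same proportions."""
        denom = 1
        for f in (self.a, self.h, self.b):
            denom = denom * f.denominator // _gcd(denom, f.denominator)
        ints = [int(f * denom) for f in (self.a, self.h, self.b)]
        g = 0
        for v in ints:
            g = _gcd(g, v)
        g = g or 1
        return tuple(v // g for v in ints)  # type: ignore[return-value]

    def allele_ratio(self) -> tuple[Fraction, Fraction]:
        """Ratio of parental A to parental B alleles."""
        return 2 * self.a + self.h, 2 * self.b + self.h


def _gcd(a: int, b: int) -> int:
    while b:
        a, b = b, a % b
    return a


# ----------------------------------------------------------------------
def pollen_compatible(pollen: PollenHaplotype) -> bool:
    """Can this pollen grain effect a self-fertilization?

    Compatibility is decided by the pollen's own haploid genotype at *Z*
    alone: the A allele expresses self-fertility, the B allele blocks
    fertilization.  The *S5* allele of the pollen is irrelevant.
    """
    return pollen.z == "A"


def stigma_selfable(stigma: LocusGenotype) -> bool:
    """Does this stigma permit selfing?  The A allele at *S5* is dominant."""
    if stigma.locus != "S5":
        raise ValueError("stigma selfability is decided at the S5 locus")
    return "A" in stigma.alleles


# ----------------------------------------------------------------------
def expected_f2_ratio(locus: str, selection: bool = True) -> GenotypeRatio:
    """Expected F2 genotype ratio at ``locus`` after selfing a heterozygous F1.

    Egg gametes segregate 1:1.  Pollen gametes segregate 1:1 but, when
    ``selection`` is on and the locus is *Z*, B-carrying pollen is excluded
    (pollen-side gametophytic selection).  *S5* stigma selection does not act
    in the F1 self (the F1 stigma is heterozygous, hence selfable), so the
    *S5* ratio stays Mendelian.
    """
    if locus not in _LOCI:
        raise ValueError(f"unknown locus {locus!r}")
    counts = {"A": Fraction(0), "H": Fraction(0), "B": Fraction(0)}
    for egg, pollen in product(_ALLELES, repeat=2):
        if selection and locus == "Z" and not pollen_compatible(
            PollenHaplotype(z=pollen, s5="A")
        ):
            continue
        key = {("A", "A"): "A", ("B", "B"): "B"}.get((egg, pollen), "H")
        counts[key] += 1
    return GenotypeRatio(counts["A"], counts["H"], counts["B"])


def expected_f3_ratio_s5(
    stigma_selection: bool = True,
) -> tuple[GenotypeRatio, tuple[Fraction, Fraction]]:
    """Expected pooled F3 genotype and allele ratio at *S5* after selfing an F2.

    The F2 segregates 1 AA : 2 AB : 1 BB at *S5*.  With stigma selection,
    BB plants cannot self and contribute nothing; AA and AB plants each
    contribute equally sized selfed families (pollen unrestricted at *S5*).
    Returns the pooled genotype ratio and the parental A:B allele ratio.
    """
    f2_classes = {("A", "A"): Fraction(1, 4), ("A", "B"): Fraction(1, 2),
                  ("B", "B"): Fraction(1, 4)}
    counts = {"A": Fraction(0), "H": Fraction(0), "B": Fraction(0)}
    selfable_weight = Fraction(0)
    for alleles, weight in f2_classes.items():
        parent = LocusGenotype(locus="S5", alleles=alleles)
        if stigma_selection and not stigma_selfable(parent):
            continue
        selfable_weight += weight
    for alleles, weight in f2_classes.items():
        parent = LocusGenotype(locus="S5", alleles=alleles)
        if stigma_selection and not stigma_selfable(parent):
            continue
        family_weight = weight / selfable_weight  # equal family sizes
        for egg, pollen in product(parent.alleles, repeat=2):
            key = {("A", "A"): "A", ("B", "B"): "B"}.get((egg, pollen), "H")
            counts[key] += family_weight * Fraction(1, 4)
    ratio = GenotypeRatio(counts["A"], counts["H"], counts["B"])
    return ratio, ratio.allele_ratio()


def multivalent_viable_fraction(model: MultivalentModel) -> Fraction:
    """Fraction of functional gametes from a ring multivalent.

    Enumerates all ``2**n_pairs`` gamete types (each homologous pair
    contributes one chromosome, independently and equiprobably); a gamete is
    functional iff all contributed chromosomes derive from one parental
    species.  Equals ``2**(1 - n_pairs)`` in closed form; for the
    three-pair hexavalent this is 2/8 = 25 %.
    """
    total = 0
    viable = 0
    for combo in product((0, 1), repeat=model.n_pairs):
        total += 1
        if len(set(combo)) == 1:
            viable += 1
    return Fraction(viable, total)
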