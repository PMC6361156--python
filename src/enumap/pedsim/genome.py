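"""Genome, mutagen and causal-allele specifications for simulation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

BASES = ("A", "C", "G", "T")

#: Default point-mutation spectrum of an alkylating mutagen: biased toward
#: A:T base pairs, with the A->G / T->C transition carrying half the mass
#: of its row.  Rows are reference bases, columns alternate bases.
DEFAULT_ENU_SPECTRUM: Mapping[str, Mapping[str, float]] = {
    "A": {"G": 0.50, "T": 0.25, "C": 0.25},
    "T": {"C": 0.50, "A": 0.25, "G": 0.25},
    "G": {"A": 0.50, "C": 0.25, "T": 0.25},
    "C": {"T": 0.50, "G": 0.25, "A": 0.25},
}


@dataclass(frozen=True)
class GenomeSpec:
    """A toy genome: chromosome sizes, a uniform genetic map and base mix.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.
    recombination_rate:
        Uniform map density in cM per Mb (1.0 means 1 Mb == 1 cM).
    base_composition:
        Probabilities of A, C, G, T used when sequence is generated or a
        reference base must be drawn outside any explicit sequence.
    """

    chromosomes: Tuple[Tuple[str, int], ...]
    recombination_rate: float = 1.0
    base_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must have at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if any(p < 0 for p in self.base_composition):
            raise ValueError("base_composition entries must be >= 0")

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def morgans(self, chrom: str) -> float:
        """Expected crossover count per meiosis for one chromosome."""
        return self.length_of(chrom) / 1e6 * self.recombination_rate / 100.0


@dataclass(frozen=True)
class EnuModel:
    """Poisson burden of mutagen-induced point mutations in one founder genome."""

    mutations_per_genome: float
    spectrum: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_ENU_SPECTRUM
    )

    def __post_init__(self) -> None:
        if self.mutations_per_genome < 0:
            raise ValueError("mutations_per_genome must be >= 0")
        for ref, row in self.spectrum.items():
            if ref not in BASES:
                raise ValueError(f"unknown reference base {ref!r}")
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"spectrum row for {ref!r} must sum to 1")
            if ref in row:
                raise ValueError(f"spectrum row for {ref!r} must not contain {ref!r}")


@dataclass(frozen=True)
class CausalPlant:
    """The planted recessive causal substitution and where it lives."""

    chromosome: str
    position: int  # 1-based bp
    ref_allele: str
    alt_allele: str
    gene: str
    cds_position: int  # 1-based within the planted CDS
    inheritance: str = "recessive"
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("alt allele must differ from ref allele")
        if self.position < 1 or self.cds_position < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        if self.inheritance != "recessive":
            raise ValueError("only recessive inheritance is modelled")
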