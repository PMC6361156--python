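"""The stepwise candidate-mutation filter.

Six ordered predicates, cheap to expensive, each individually toggleable:

1. site quality and per-sample depth;
2. position inside the mapped region;
3. damaging effect (missense, nonsense or canonical splice site);
4. homozygous alternate in every sequenced affected individual;
5. novelty — alternate allele absent from all control panels;
6. recessive co-segregation across the fully typed pedigree.

Steps 2-5 are pure per-variant predicates, so the surviving set is
independent of their relative order; step 6 consumes extra genotypes (the
Sanger follow-up of unsequenced relatives) supplied via a lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from enumap.assoc.regions import RegionCall
from enumap.exome.annotate import DAMAGING_EFFECTS, Annotation, annotate_effect
from enumap.exome.models import FragmentStore, GeneModel
from enumap.pedsim.pedigree import AFFECTED, UNAFFECTED


@dataclass
class Variant:
    """A called exome variant with partial per-individual genotypes."""

    chromosome: str
    position: int
    ref: str
    alt: str
    qual: Optional[float] = None
    genotypes: Dict[str, int] = field(default_factory=dict)  # id -> dosage, -1 missing
    depths: Dict[str, int] = field(default_factory=dict)
    id: str = "."

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.position < 1:
            raise ValueError("positions are 1-based")


@dataclass(frozen=True)
class CascadeStep:
    name: str
    description: str
    n_in: int
    n_out: int


@dataclass
class CascadeReport:
    steps: List[CascadeStep] = field(default_factory=list)

    def add(self, name: str, description: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError("cascade steps cannot add variants")
        if self.steps and n_in != self.steps[-1].n_out:
            raise ValueError("cascade step input must match previous output")
        self.steps.append(CascadeStep(name, description, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.name,
                    "description": s.description,
                    "variants_in": s.n_in,
                    "variants_out": s.n_out,
                }
                for s in self.steps
            ]
        )


@dataclass(frozen=True)
class CascadeThresholds:
    """Step-1 thresholds plus per-step enable switches."""

    min_qual: float = 20.0
    min_depth: int = 5
    enabled: Tuple[str, ...] = (
        "quality",
        "region",
        "effect",
        "recessive",
        "novelty",
        "segregation",
    )


def segregation_test(
    genotypes: Dict[str, int],
    phenotypes: Dict[str, str],
    model: str = "recessive",
) -> Tuple[bool, pd.DataFrame]:
    """Recessive co-segregation over all typed individuals.

    Passes iff every genotyped affected individual is homozygous alternate
    and no genotyped unaffected individual is.  Individuals missing a
    genotype are skipped but listed in the detail table.  Raises when no
    affected individual is genotyped (the test would be vacuous).
    """
    if model != "recessive":
        raise ValueError("only the recessive model is implemented")
    rows = []
    passes = True
    n_affected_typed = 0
    for ind_id, phen in phenotypes.items():
        dose = genotypes.get(ind_id, -1)
        if dose < 0:
            rows.append({"individual": ind_id, "phenotype": phen, "dosage": None, "consistent": None})
            continue
        if phen == AFFECTED:
            n_affected_typed += 1
            ok = dose == 2
        elif phen == UNAFFECTED:
            ok = dose != 2
        else:
            rows.append({"individual": ind_id, "phenotype": phen, "dosage": dose, "consistent": None})
            continue
        passes &= ok
        rows.append({"individual": ind_id, "phenotype": phen, "dosage": dose, "consistent": ok})
    if n_affected_typed == 0:
        raise ValueError("no genotyped affected individual: segregation test is uninformative")
    return passes, pd.DataFrame(rows)


def novelty_check(v: Variant, control_panels: Sequence[pd.DataFrame]) -> bool:
    """True iff the alternate allele is absent from every control panel.

    Panels are DataFrames with ``chrom, pos, ref, alt`` plus one dosage
    column per control individual (as produced by the control simulator or
    a VCF ingest).  Empty panels are vacuously novel.
    """
    for panel in control_panels:
        if panel is None or panel.empty:
            continue
        hit = panel[
            (panel["chrom"] == v.chromosome)
            & (panel["pos"] == v.position)
            & (panel["alt"] == v.alt)
        ]
        if hit.empty:
            continue
        dosage_cols = [
            c for c in panel.columns if c not in ("chrom", "pos", "ref", "alt", "kind")
        ]
        if (hit[dosage_cols].to_numpy() > 0).any():
            return False
    return True


GenotypeLookup = Callable[[Variant], Dict[str, int]]


def filter_cascade(
    variants: Sequence[Variant],
    region: RegionCall,
    genes: Sequence[GeneModel],
    sequences: FragmentStore,
    control_panels: Sequence[pd.DataFrame],
    phenotypes: Dict[str, str],
    sequenced_affected: Sequence[str],
    thresholds: CascadeThresholds = CascadeThresholds(),
    full_genotypes: Optional[GenotypeLookup] = None,
) -> Tuple[pd.DataFrame, CascadeReport]:
    """Run the six-step cascade; returns the candidate table and report.

    ``full_genotypes`` supplies follow-up genotypes of the whole pedigree
    for the final segregation step (variant -> id -> dosage); when absent,
    segregation is evaluated on the genotypes already attached to each
    variant.  The candidate table mirrors the published format: gene,
    position, alleles, HGVS c./p. labels and effect.
    """
    if region is None:
        raise ValueError("a mapped region is required (none was called)")
    report = CascadeReport()
    current: List[Variant] = list(variants)
    annotations: Dict[int, Annotation] = {}

    def step(name: str, description: str, predicate) -> None:
        nonlocal current
        n_in = len(current)
        if name in thresholds.enabled:
            current = [v for v in current if predicate(v)]
        report.add(name, description, n_in, len(current))

    step(
        "quality",
        f"QUAL >= {thresholds.min_qual} and every sequenced depth >= {thresholds.min_depth}",
        lambda v: (v.qual is None or v.qual >= thresholds.min_qual)
        and all(d >= thresholds.min_depth for d in v.depths.values()),
    )
    step(
        "region",
        f"inside {region.chromosome}:{region.start}-{region.end}",
        lambda v: region.contains(v.chromosome, v.position),
    )

    def damaging(v: Variant) -> bool:
        ann = annotate_effect(v.chromosome, v.position, v.ref, v.alt, genes, sequences)
        annotations[id(v)] = ann
        return ann.effect in DAMAGING_EFFECTS

    step("effect", "missense, nonsense or splice-site", damaging)
    step(
        "recessive",
        "homozygous alternate in all sequenced affected individuals",
        lambda v: all(v.genotypes.get(s, -1) == 2 for s in sequenced_affected),
    )
    step(
        "novelty",
        "alternate allele absent from control panels",
        lambda v: novelty_check(v, control_panels),
    )

    def co_segregates(v: Variant) -> bool:
        genotypes = full_genotypes(v) if full_genotypes is not None else v.genotypes
        passes, _ = segregation_test(genotypes, phenotypes)
        return passes

    step("segregation", "recessive co-segregation in the whole pedigree", co_segregates)

    rows = []
    for v in current:
        ann = annotations.get(id(v)) or annotate_effect(
            v.chromosome, v.position, v.ref, v.alt, genes, sequences
        )
        rows.append(
            {
                "gene": ann.gene,
                "chrom": v.chromosome,
                "pos": v.position,
                "ref": v.ref,
                "alt": v.alt,
                "hgvs_c": ann.hgvs_c,
                "hgvs_p": ann.hgvs_p,
                "effect": ann.effect,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene", "chrom", "pos", "ref", "alt", "hgvs_c", "hgvs_p", "effect"]
    )
    return table, report


def count_genes_in_region(genes: Iterable[GeneModel], region: RegionCall) -> int:
    """Number of gene models overlapping the region by at least one base."""
    return sum(
        1
        for g in genes
        if g.chrom == region.chromosome
        and g.start <= region.end
        and g.end >= region.start
    )
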