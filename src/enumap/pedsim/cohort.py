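"""One-call simulation of a complete mapping cohort.

Bundles the genome, gene annotation, pedigree breeding, SNP-array
genotyping, exome variant calls and control panels into a single seeded
object that the downstream stages (association scan, filter cascade,
splice analysis) can consume either in memory or from emitted files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from enumap._rng import stage_rng
from enumap.exome.models import FragmentStore, GeneModel
from enumap.io.fasta import write_fragments
from enumap.io.gff import write_gff3
from enumap.io.plink import GenotypeMatrix, write_ped_map
from enumap.pedsim.breed import (
    TruthSet,
    assign_null_phenotypes,
    assign_phenotypes,
    breed_pedigree,
    founder_haplotypes,
)
from enumap.pedsim.fixture import GeneFixture, make_duox2_like_fixture
from enumap.pedsim.genome import BASES, EnuModel, GenomeSpec
from enumap.pedsim.markers import genotype_markers
from enumap.pedsim.pedigree import AFFECTED, default_design
from enumap.pedsim.sites import (
    SiteVariant,
    build_site_map,
    place_markers,
    simulate_founder_mutations,
    uniform_maf,
)
from enumap.pedsim.variants import (
    control_panel_genotypes,
    emit_exome_vcf,
    exome_records,
    write_truth_table,
)
from enumap.splice.transcript import CODON_TABLE

_SENSE = tuple(sorted(c for c, aa in CODON_TABLE.items() if aa != "*" and c != "ATG"))


@dataclass
class SimParams:
    """Knobs of the cohort simulator (all sizes are desk-scale defaults)."""

    chromosomes: Tuple[Tuple[str, int], ...] = (
        ("chr1", 100_000_000),
        ("chr2", 80_000_000),
        ("chr3", 60_000_000),
    )
    recombination_rate: float = 1.0  # cM/Mb
    n_markers: int = 5000
    maf_range: Tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.02
    error_rate: float = 0.0
    enu_mean: float = 1500.0  # mutagen point mutations per founder genome
    n_shared_variants: int = 30
    n_background_genes: int = 150
    background_cds_range: Tuple[int, int] = (300, 2400)
    n_controls: int = 20
    n_families: int = 4
    n_affected: int = 15
    n_unaffected: int = 25
    penetrance: float = 1.0
    causal_chrom: str = "chr1"
    causal_position: int = 50_000_000
    n_sequenced_affected: int = 2
    depth_mean: float = 40.0
    null_model: bool = False  # no causal allele; random phenotype labels


@dataclass
class Cohort:
    """A simulated cohort plus every derived artefact the pipeline needs."""

    params: SimParams
    spec: GenomeSpec
    truth: TruthSet
    matrix: GenotypeMatrix
    fixture: Optional[GeneFixture]
    genes: List[GeneModel]
    fragments: FragmentStore
    control_panel: "object"  # DataFrame; typed loosely to avoid heavy import
    sequenced: List[str]
    phenotypes: Dict[str, str] = field(default_factory=dict)

    def full_genotypes(self, chrom: str, pos: int) -> Dict[str, int]:
        """Follow-up genotypes of the whole pedigree at one site."""
        return self.truth.genotype_at(chrom, pos)

    def exon_targets(self) -> List[Tuple[str, int, int]]:
        return [(g.chrom, s, e) for g in self.genes for s, e in g.exons]


def _random_gene(
    rng: np.random.Generator,
    spec: GenomeSpec,
    gene_id: str,
    cds_range: Tuple[int, int],
    occupied: Dict[str, List[Tuple[int, int]]],
) -> Optional[Tuple[GeneModel, str, int]]:
    """One single-exon background gene avoiding existing loci; None if the
    placement attempt keeps colliding."""
    lengths = np.array([length for _, length in spec.chromosomes], dtype=float)
    flank = 50
    for _ in range(20):
        ci = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
        chrom, chrom_len = spec.chromosomes[ci]
        n_codons = int(rng.integers(cds_range[0] // 3, cds_range[1] // 3 + 1))
        cds_len = 3 * n_codons
        start = int(rng.integers(flank + 1, chrom_len - cds_len - flank))
        lo, hi = start - flank, start + cds_len - 1 + flank
        if any(s <= hi and e >= lo for s, e in occupied.get(chrom, [])):
            continue
        occupied.setdefault(chrom, []).append((lo, hi))
        picks = rng.integers(0, len(_SENSE), size=n_codons - 2)
        cds = "ATG" + "".join(_SENSE[i] for i in picks) + "TAA"
        fragment = (
            "".join(np.array(list(BASES))[rng.integers(0, 4, size=flank)])
            + cds
            + "".join(np.array(list(BASES))[rng.integers(0, 4, size=flank)])
        )
        gene = GeneModel(
            gene_id=gene_id,
            chrom=chrom,
            exons=((start, start + cds_len - 1),),
            cds=((start, start + cds_len - 1),),
        )
        return gene, fragment, start - flank
    return None


def simulate_cohort(params: SimParams, seed: int) -> Cohort:
    """Simulate a full cohort from a single root seed (deterministic)."""
    spec = GenomeSpec(
        chromosomes=params.chromosomes,
        recombination_rate=params.recombination_rate,
    )

    fragments = FragmentStore()
    genes: List[GeneModel] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {}

    fixture: Optional[GeneFixture] = None
    if not params.null_model:
        fixture = make_duox2_like_fixture(
            chrom=params.causal_chrom, causal_position=params.causal_position
        )
        genes.append(fixture.gene)
        frag_chrom, frags = next(iter(fixture.fragments.fragments().items()))
        start, end, seq = frags[0]
        fragments.add(frag_chrom, start, seq)
        occupied.setdefault(frag_chrom, []).append((start, end))

    rng_genes = stage_rng(seed, "genes")
    for i in range(params.n_background_genes):
        placed = _random_gene(
            rng_genes, spec, f"bg{i + 1:04d}", params.background_cds_range, occupied
        )
        if placed is None:
            continue
        gene, fragment, frag_start = placed
        genes.append(gene)
        fragments.add(gene.chrom, frag_start, fragment)

    rng_enu = stage_rng(seed, "mutations")
    enu = EnuModel(mutations_per_genome=params.enu_mean)
    background = simulate_founder_mutations(
        spec, enu, rng_enu, sequence_lookup=fragments.base_at
    )
    causal = fixture.plant if fixture is not None else None
    if causal is not None:
        background = [
            v
            for v in background
            if not (v.chromosome == causal.chromosome and v.position == causal.position)
        ]

    # strain polymorphisms planted inside background gene CDS so the
    # novelty filter has genuine work to do
    shared: List[SiteVariant] = []
    taken = {(v.chromosome, v.position) for v in background}
    bg_genes = [g for g in genes if fixture is None or g.gene_id != fixture.gene.gene_id]
    if bg_genes:
        for _ in range(params.n_shared_variants):
            g = bg_genes[int(rng_enu.integers(0, len(bg_genes)))]
            pos = int(rng_enu.integers(g.cds[0][0], g.cds[0][1] + 1))
            if (g.chrom, pos) in taken:
                continue
            taken.add((g.chrom, pos))
            ref = fragments.base_at(g.chrom, pos)
            alts = [b for b in BASES if b != ref]
            alt = alts[int(rng_enu.integers(0, 3))]
            shared.append(SiteVariant(g.chrom, pos, ref, alt, kind="shared"))

    rng_markers = stage_rng(seed, "markers")
    marker_rows = place_markers(
        spec, params.n_markers, uniform_maf(*params.maf_range), rng_markers
    )
    marker_rows = [
        r for r in marker_rows if (r["chrom"], r["pos"]) not in taken
    ]
    sites, _ = build_site_map(spec, marker_rows, background + shared, causal=causal)

    design = default_design(
        n_families=params.n_families,
        n_affected=params.n_affected,
        n_unaffected=params.n_unaffected,
        condition_on_phenotype=not params.null_model,
    )
    shared_freq = {
        chrom: stage_rng(seed, f"sharedfreq:{chrom}").uniform(
            0.05, 0.5, size=int((sites.tables[chrom]["kind"] == "shared").sum())
        )
        for chrom in sites.chromosomes
    }
    rng_founders = stage_rng(seed, "founders")
    haps = founder_haplotypes(design, sites, rng_founders, shared_freq=shared_freq)
    rng_breed = stage_rng(seed, "breeding")
    truth = breed_pedigree(
        design, spec, sites, haps, rng_breed, causal=causal,
        background_variants=background + shared,
    )

    if params.null_model:
        phenotypes = assign_null_phenotypes(
            truth, params.n_affected, stage_rng(seed, "phenotypes")
        )
    else:
        plant = causal
        if params.penetrance != plant.penetrance:
            plant = replace(plant, penetrance=params.penetrance)
        phenotypes = assign_phenotypes(truth, plant, stage_rng(seed, "phenotypes"))

    matrix = genotype_markers(
        truth, params.missing_rate, params.error_rate, stage_rng(seed, "genotyping")
    )
    control_panel = control_panel_genotypes(
        truth, params.n_controls, stage_rng(seed, "controls")
    )
    affected = [i.id for i in truth.pedigree.individuals if i.phenotype == AFFECTED]
    sequenced = affected[: params.n_sequenced_affected]
    return Cohort(
        params=params,
        spec=spec,
        truth=truth,
        matrix=matrix,
        fixture=fixture,
        genes=genes,
        fragments=fragments,
        control_panel=control_panel,
        sequenced=sequenced,
        phenotypes=phenotypes,
    )


def emit_cohort(cohort: Cohort, outdir: Path, seed: int) -> Dict[str, Path]:
    """Write the cohort's file artefacts; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    ped, mp = write_ped_map(cohort.matrix, cohort.truth.pedigree, outdir / "cohort")
    paths["ped"], paths["map"] = ped, mp
    paths["vcf"] = emit_exome_vcf(
        cohort.truth,
        cohort.sequenced,
        outdir / "exome.vcf",
        depth_mean=cohort.params.depth_mean,
        rng=stage_rng(seed, "exome_depths"),
    )
    paths["fasta"] = write_fragments(cohort.fragments, outdir / "genome_fragments.fasta")
    paths["gff"] = write_gff3(cohort.genes, outdir / "genes.gff3")
    paths["truth"] = write_truth_table(cohort.truth, outdir / "truth.tsv")
    cohort.control_panel.to_csv(outdir / "controls.tsv", sep="\t", index=False)
    paths["controls"] = outdir / "controls.tsv"
    return paths
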