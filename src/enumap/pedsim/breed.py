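"""Gene-dropping through a pedigree with recombination.

Haplotypes are ``int8`` arrays over the sites of one chromosome (0 = ref
allele, 1 = alt/minor allele).  A transmitted gamete is a recombinant of
the parent's two haplotypes: the crossover count is Poisson with mean
equal to the chromosome's map length in Morgans (Haldane, no
interference), crossover positions are uniform in bp, and the starting
haplotype is a fair coin.

The breeder can *condition* the genotype at the single causal site for
designated individuals (carrier-by-design, affected-by-design).  Because
the two complementary gametes of a given crossover realisation are equally
likely, conditioning is implemented by choosing the starting haplotype
compatible with the required causal allele — the marginal distribution of
the rest of the gamete remains exactly Mendelian given that allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from enumap.pedsim.genome import CausalPlant, GenomeSpec
from enumap.pedsim.pedigree import (
    AFFECTED,
    REQ_HET,
    REQ_HOM_ALT,
    REQ_NOT_HOM_ALT,
    BreedingDesign,
    Pedigree,
    UNAFFECTED,
)
from enumap.pedsim.sites import SiteMap, SiteVariant

# haplotype set for one individual: chrom -> (2, n_sites) int8
Haplotypes = Dict[str, np.ndarray]


@dataclass
class TruthSet:
    """Everything the simulator knows: full diplotypes plus the plant."""

    pedigree: Pedigree
    sites: SiteMap
    spec: GenomeSpec
    causal: Optional[CausalPlant]
    # chrom -> (n_individuals, 2, n_sites) int8, individuals in pedigree order
    diplotypes: Dict[str, np.ndarray]
    background_variants: List[SiteVariant] = field(default_factory=list)

    def index_of_individual(self, ind_id: str) -> int:
        return self.pedigree.ids.index(ind_id)

    def dosage(self, chrom: str) -> np.ndarray:
        """(n_sites, n_individuals) alt-allele dosage matrix."""
        return self.diplotypes[chrom].sum(axis=1).T.astype(np.int8)

    def genotype_at(self, chrom: str, pos: int) -> Dict[str, int]:
        i = self.sites.index_of(chrom, pos)
        d = self.diplotypes[chrom][:, :, i].sum(axis=1)
        return {ind_id: int(v) for ind_id, v in zip(self.pedigree.ids, d)}

    def causal_dosage(self) -> Dict[str, int]:
        if self.causal is None:
            raise ValueError("no causal variant planted")
        return self.genotype_at(self.causal.chromosome, self.causal.position)


def founder_haplotypes(
    design: BreedingDesign,
    sites: SiteMap,
    rng: np.random.Generator,
    shared_freq: Optional[Dict[str, np.ndarray]] = None,
) -> Dict[str, Haplotypes]:
    """Draw founder haplotypes for every founder in the design.

    Marker alleles are Bernoulli(maf) per haplotype; ``shared`` strain
    polymorphisms are Bernoulli of their population frequency (from
    ``shared_freq``, keyed by chromosome, aligned to the site table rows of
    that kind); mutagen-induced (``enu``) and ``causal`` alleles are absent
    from every founder except the mutagenized one, which carries each on
    one uniformly chosen haplotype (heterozygous).
    """
    haps: Dict[str, Haplotypes] = {}
    for founder in design.pedigree.founders():
        per_chrom: Haplotypes = {}
        for chrom in sites.chromosomes:
            table = sites.tables[chrom]
            n = len(table)
            h = np.zeros((2, n), dtype=np.int8)
            is_marker = (table["kind"] == "marker").to_numpy()
            if is_marker.any():
                maf = table.loc[is_marker, "maf"].to_numpy()
                h[:, is_marker] = (rng.random((2, is_marker.sum())) < maf).astype(np.int8)
            is_shared = (table["kind"] == "shared").to_numpy()
            if is_shared.any() and shared_freq is not None:
                freq = shared_freq[chrom]
                h[:, is_shared] = (rng.random((2, is_shared.sum())) < freq).astype(np.int8)
            if founder.id == design.founder_carrier:
                mut = table["kind"].isin(["enu", "causal"]).to_numpy()
                which = rng.integers(0, 2, size=int(mut.sum()))
                idx = np.flatnonzero(mut)
                h[which, idx] = 1
            per_chrom[chrom] = h
        haps[founder.id] = per_chrom
    return haps


def _draw_gamete(
    rng: np.random.Generator,
    positions: np.ndarray,
    hap_pair: np.ndarray,
    length_bp: int,
    morgans: float,
    want: Optional[int] = None,
    causal_idx: Optional[int] = None,
) -> np.ndarray:
    """One recombinant gamete; optionally conditioned on the causal allele."""
    k = int(rng.poisson(morgans)) if morgans > 0 else 0
    if k:
        cx = np.sort(rng.uniform(0, length_bp, size=k))
        parity = np.searchsorted(cx, positions).astype(np.int64)
    else:
        parity = np.zeros(len(positions), dtype=np.int64)
    start = int(rng.integers(0, 2))
    if want is not None and causal_idx is not None:
        a0, a1 = hap_pair[:, causal_idx]
        if a0 != a1:
            p = int(parity[causal_idx]) % 2
            # pick the start so that source haplotype at the causal site
            # carries the wanted allele
            desired_src = 0 if a0 == want else 1
            start = (desired_src - p) % 2
        # homozygous parent: nothing to condition on
    src = (parity + start) % 2
    return hap_pair[src, np.arange(len(positions))]


def breed_pedigree(
    design: BreedingDesign,
    spec: GenomeSpec,
    sites: SiteMap,
    founder_haps: Dict[str, Haplotypes],
    seed_or_rng,
    causal: Optional[CausalPlant] = None,
    background_variants: Optional[List[SiteVariant]] = None,
) -> TruthSet:
    """Drop founder haplotypes through the pedigree.

    Raises if a founder lacks haplotypes.  Genotype requirements recorded
    in the design are honoured at the causal site (see module docstring);
    they are ignored when no causal variant is planted.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    ped = design.pedigree
    for founder in ped.founders():
        if founder.id not in founder_haps:
            raise ValueError(f"missing haplotypes for founder {founder.id!r}")

    causal_chrom = causal.chromosome if causal is not None else None
    causal_idx = (
        sites.index_of(causal.chromosome, causal.position) if causal is not None else None
    )

    hap_store: Dict[str, Haplotypes] = {}
    order = ped.ids
    for ind in ped.individuals:
        if ind.is_founder:
            hap_store[ind.id] = founder_haps[ind.id]
            continue
        sire_h = hap_store[ind.sire]
        dam_h = hap_store[ind.dam]
        req = design.requirements.get(ind.id) if causal is not None else None
        want_sire = want_dam = None
        if req == REQ_HOM_ALT:
            want_sire = want_dam = 1
        elif req == REQ_HET:
            # exactly one transmitted alt: choose uniformly among the
            # parents that actually carry the allele
            sire_carries = bool(sire_h[causal_chrom][:, causal_idx].any())
            dam_carries = bool(dam_h[causal_chrom][:, causal_idx].any())
            coin = int(rng.integers(0, 2))
            if sire_carries and (coin or not dam_carries):
                want_sire, want_dam = 1, 0
            elif dam_carries:
                want_sire, want_dam = 0, 1
        per_chrom: Haplotypes = {}
        for chrom in sites.chromosomes:
            positions = sites.positions(chrom)
            length_bp = spec.length_of(chrom)
            morgans = spec.morgans(chrom)
            on_causal = chrom == causal_chrom
            g_sire = _draw_gamete(
                rng, positions, sire_h[chrom], length_bp, morgans,
                want=want_sire if on_causal else None,
                causal_idx=causal_idx if on_causal else None,
            )
            g_dam = _draw_gamete(
                rng, positions, dam_h[chrom], length_bp, morgans,
                want=want_dam if on_causal else None,
                causal_idx=causal_idx if on_causal else None,
            )
            if (
                req == REQ_NOT_HOM_ALT
                and on_causal
                and g_sire[causal_idx] == 1
                and g_dam[causal_idx] == 1
            ):
                # resample one transmission conditioned on the ref allele;
                # both G2 parents are het by design so this is always possible
                if int(rng.integers(0, 2)):
                    g_sire = _draw_gamete(
                        rng, positions, sire_h[chrom], length_bp, morgans,
                        want=0, causal_idx=causal_idx,
                    )
                else:
                    g_dam = _draw_gamete(
                        rng, positions, dam_h[chrom], length_bp, morgans,
                        want=0, causal_idx=causal_idx,
                    )
            per_chrom[chrom] = np.stack([g_sire, g_dam])
        hap_store[ind.id] = per_chrom

    diplo: Dict[str, np.ndarray] = {}
    for chrom in sites.chromosomes:
        diplo[chrom] = np.stack([hap_store[i][chrom] for i in order]).astype(np.int8)
    return TruthSet(
        pedigree=ped,
        sites=sites,
        spec=spec,
        causal=causal,
        diplotypes=diplo,
        background_variants=list(background_variants or []),
    )


def assign_phenotypes(
    truth: TruthSet,
    plant: CausalPlant,
    seed_or_rng,
) -> Dict[str, str]:
    """Phenotype map under a recessive model with the plant's penetrance.

    Homozygous-alt individuals are affected with probability
    ``plant.penetrance``; everyone else is unaffected.  The map is also
    written back onto the pedigree.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    dosages = truth.genotype_at(plant.chromosome, plant.position)
    phenotypes: Dict[str, str] = {}
    for ind_id, dose in dosages.items():
        if dose == 2 and rng.random() < plant.penetrance:
            phenotypes[ind_id] = AFFECTED
        else:
            phenotypes[ind_id] = UNAFFECTED
    truth.pedigree.set_phenotypes(phenotypes)
    return phenotypes


def assign_null_phenotypes(
    truth: TruthSet,
    n_affected: int,
    seed_or_rng,
    generation: str = "G3",
) -> Dict[str, str]:
    """Random phenotype labels independent of genotype (null calibration).

    ``n_affected`` individuals of the target generation are labelled
    affected uniformly at random; all others unaffected.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    cohort = [i.id for i in truth.pedigree.individuals if i.generation == generation]
    if n_affected > len(cohort):
        raise ValueError("n_affected exceeds cohort size")
    chosen = set(rng.choice(cohort, size=n_affected, replace=False))
    phenotypes = {
        ind.id: AFFECTED if ind.id in chosen else UNAFFECTED
        for ind in truth.pedigree.individuals
    }
    truth.pedigree.set_phenotypes(phenotypes)
    return phenotypes
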