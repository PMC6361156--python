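"""Pedigree structure and the default multi-family breeding design."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

MALE = "male"
FEMALE = "female"

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"


@dataclass
class Individual:
    """One animal: identity, parent links, sex and phenotype."""

    id: str
    sire: Optional[str] = None
    dam: Optional[str] = None
    sex: str = MALE
    generation: Optional[str] = None  # "G0".."G3" for constructed designs
    phenotype: str = UNKNOWN

    def __post_init__(self) -> None:
        if (self.sire is None) != (self.dam is None):
            raise ValueError(f"{self.id}: must have both parents or neither")
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"{self.id}: sex must be 'male' or 'female'")
        if self.phenotype not in (AFFECTED, UNAFFECTED, UNKNOWN):
            raise ValueError(f"{self.id}: bad phenotype {self.phenotype!r}")

    @property
    def is_founder(self) -> bool:
        return self.sire is None


class Pedigree:
    """An ordered collection of individuals with resolved parent links.

    Individuals must be listed parents-before-offspring; this ordering
    doubles as the acyclicity proof and is relied on by the breeder.

    Parameters
    ----------
    individuals:
        Topologically ordered individuals.
    families:
        Optional mapping of individual id to a family label (e.g. the four
        nuclear families of a mapping cohort).  Unlisted individuals are
        assigned family ``"0"``.
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        families: Optional[Dict[str, str]] = None,
    ) -> None:
        self.individuals: List[Individual] = list(individuals)
        self._by_id: Dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in self._by_id:
                    raise ValueError(
                        f"{ind.id}: parent {parent!r} missing or listed after offspring"
                    )
            if ind.sire is not None:
                if self._by_id[ind.sire].sex != MALE:
                    raise ValueError(f"{ind.id}: sire {ind.sire!r} is not male")
                if self._by_id[ind.dam].sex != FEMALE:
                    raise ValueError(f"{ind.id}: dam {ind.dam!r} is not female")
            self._by_id[ind.id] = ind
        self.families: Dict[str, str] = dict(families or {})
        for ind in self.individuals:
            self.families.setdefault(ind.id, "0")

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    def __getitem__(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    @property
    def ids(self) -> List[str]:
        return [ind.id for ind in self.individuals]

    def founders(self) -> List[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def nonfounders(self) -> List[Individual]:
        return [ind for ind in self.individuals if not ind.is_founder]

    def affected(self) -> List[Individual]:
        return [ind for ind in self.individuals if ind.phenotype == AFFECTED]

    def trios(self) -> List[Tuple[Individual, Individual, Individual]]:
        """(sire, dam, child) triples for every non-founder."""
        return [
            (self._by_id[ind.sire], self._by_id[ind.dam], ind)
            for ind in self.individuals
            if not ind.is_founder
        ]

    def set_phenotypes(self, phenotypes: Dict[str, str]) -> None:
        for ind_id, value in phenotypes.items():
            self._by_id[ind_id].phenotype = value


# requirement codes used by the breeder to condition causal-site genotypes
REQ_HET = "het"
REQ_HOM_ALT = "hom_alt"
REQ_NOT_HOM_ALT = "not_hom_alt"


@dataclass
class BreedingDesign:
    """A pedigree plus per-individual causal-genotype requirements."""

    pedigree: Pedigree
    requirements: Dict[str, str] = field(default_factory=dict)
    founder_carrier: str = ""  # id of the mutagenized founder


def _split_counts(total: int, n_families: int) -> List[int]:
    base, extra = divmod(total, n_families)
    return [base + (1 if i < extra else 0) for i in range(n_families)]


def default_design(
    n_families: int = 4,
    n_affected: int = 15,
    n_unaffected: int = 25,
    condition_on_phenotype: bool = True,
) -> BreedingDesign:
    """Three-generation design: one mutagenized founder male crossed to two
    wild-type females, heterozygous carriers propagated to ``n_families``
    carrier-pair families whose offspring form the genotyped cohort.

    With ``condition_on_phenotype`` the final generation is conditioned to
    contain exactly ``n_affected`` homozygous-mutant and ``n_unaffected``
    carrier/wild-type offspring (the cohort a mapping study would recruit).
    Without it the final generation segregates freely — the configuration
    used for null calibration.
    """
    if n_families < 1:
        raise ValueError("need at least one family")
    inds: List[Individual] = []
    req: Dict[str, str] = {}
    fam: Dict[str, str] = {}

    founder = Individual("G0_M1", sex=MALE, generation="G0", phenotype=UNAFFECTED)
    inds.append(founder)
    dams0 = []
    for i in (1, 2):
        d = Individual(f"G0_F{i}", sex=FEMALE, generation="G0", phenotype=UNAFFECTED)
        inds.append(d)
        dams0.append(d.id)
    for ind in inds:
        fam[ind.id] = "FND"

    # G1: two carrier sons and two carrier daughters
    g1 = []
    for i in range(4):
        ind = Individual(
            f"G1_{i + 1}",
            sire=founder.id,
            dam=dams0[i % 2],
            sex=MALE if i % 2 == 0 else FEMALE,
            generation="G1",
            phenotype=UNAFFECTED,
        )
        inds.append(ind)
        req[ind.id] = REQ_HET
        fam[ind.id] = "FND"
        g1.append(ind)
    g1_males = [i.id for i in g1 if i.sex == MALE]
    g1_females = [i.id for i in g1 if i.sex == FEMALE]

    # G2: one carrier pair per family; sires and dams drawn from opposite
    # G0 dams to avoid full-sib matings where the design allows it.
    pairs = []
    for f in range(n_families):
        sire = Individual(
            f"G2_F{f + 1}_M",
            sire=g1_males[f % len(g1_males)],
            dam=g1_females[(f + 1) % len(g1_females)],
            sex=MALE,
            generation="G2",
            phenotype=UNAFFECTED,
        )
        dam = Individual(
            f"G2_F{f + 1}_F",
            sire=g1_males[(f + 1) % len(g1_males)],
            dam=g1_females[f % len(g1_females)],
            sex=FEMALE,
            generation="G2",
            phenotype=UNAFFECTED,
        )
        for ind in (sire, dam):
            inds.append(ind)
            req[ind.id] = REQ_HET
            fam[ind.id] = f"FAM{f + 1}"
        pairs.append((sire.id, dam.id))

    aff_per_fam = _split_counts(n_affected, n_families)
    unaff_per_fam = _split_counts(n_unaffected, n_families)
    for f, (sire_id, dam_id) in enumerate(pairs):
        child_no = 0
        for kind, count in (("A", aff_per_fam[f]), ("U", unaff_per_fam[f])):
            for _ in range(count):
                child_no += 1
                ind = Individual(
                    f"G3_F{f + 1}_{child_no:02d}",
                    sire=sire_id,
                    dam=dam_id,
                    sex=MALE if child_no % 2 else FEMALE,
                    generation="G3",
                    phenotype=UNKNOWN,
                )
                inds.append(ind)
                fam[ind.id] = f"FAM{f + 1}"
                if condition_on_phenotype:
                    req[ind.id] = REQ_HOM_ALT if kind == "A" else REQ_NOT_HOM_ALT

    return BreedingDesign(
        pedigree=Pedigree(inds, families=fam),
        requirements=req,
        founder_carrier=founder.id,
    )
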