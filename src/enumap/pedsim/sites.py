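"""Site maps: every simulated polymorphic position, typed by origin.

A :class:`SiteMap` holds, per chromosome, a sorted table of sites with one
row per position.  Three kinds of site flow through the same transmission
machinery:

``marker``
    SNP-array markers with population minor-allele frequencies.
``enu`` / ``shared``
    Exome point variants: mutagen-induced (private to the mutagenized
    founder) or strain polymorphisms shared with control populations.
``causal``
    The single planted causal substitution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from enumap.pedsim.genome import BASES, CausalPlant, EnuModel, GenomeSpec

SITE_COLUMNS = ["pos", "kind", "name", "ref", "alt", "maf"]


@dataclass(frozen=True)
class SiteVariant:
    """A point substitution at a genomic position (1-based)."""

    chromosome: str
    position: int
    ref: str
    alt: str
    kind: str = "enu"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


class SiteMap:
    """Sorted per-chromosome site tables plus index helpers."""

    def __init__(self, tables: Dict[str, pd.DataFrame]):
        self.tables: Dict[str, pd.DataFrame] = {}
        for chrom, df in tables.items():
            df = df.sort_values("pos", kind="mergesort").reset_index(drop=True)
            if df["pos"].duplicated().any():
                raise ValueError(f"duplicate site positions on {chrom}")
            self.tables[chrom] = df[SITE_COLUMNS]

    @property
    def chromosomes(self) -> List[str]:
        return list(self.tables)

    def n_sites(self, chrom: str) -> int:
        return len(self.tables[chrom])

    def positions(self, chrom: str) -> np.ndarray:
        return self.tables[chrom]["pos"].to_numpy()

    def index_of(self, chrom: str, pos: int) -> int:
        positions = self.positions(chrom)
        i = int(np.searchsorted(positions, pos))
        if i >= len(positions) or positions[i] != pos:
            raise KeyError(f"no site at {chrom}:{pos}")
        return i

    def sites_of_kind(self, *kinds: str) -> pd.DataFrame:
        frames = []
        for chrom, df in self.tables.items():
            sub = df[df["kind"].isin(kinds)].copy()
            sub.insert(0, "chrom", chrom)
            frames.append(sub)
        if not frames:
            return pd.DataFrame(columns=["chrom", *SITE_COLUMNS])
        return pd.concat(frames, ignore_index=True)


def simulate_founder_mutations(
    spec: GenomeSpec,
    enu: EnuModel,
    seed_or_rng,
    sequence_lookup: Optional[Callable[[str, int], Optional[str]]] = None,
) -> List[SiteVariant]:
    """Draw one founder genome's worth of mutagen-induced point mutations.

    The count is Poisson with mean ``enu.mutations_per_genome``; positions
    are uniform over the genome (chromosomes weighted by length);
    substitution classes follow the mutagen spectrum conditioned on the
    reference base.  Where ``sequence_lookup(chrom, pos)`` returns a base,
    that base is used as the reference; elsewhere the reference base is
    drawn from the genome's base composition.

    Deterministic for a fixed seed.  Positions colliding with an earlier
    draw are dropped (vanishingly rare at realistic densities).
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if spec.total_length <= 0:
        raise ValueError("zero-length genome")
    count = int(rng.poisson(enu.mutations_per_genome))
    lengths = np.array([length for _, length in spec.chromosomes], dtype=float)
    chrom_idx = rng.choice(len(lengths), size=count, p=lengths / lengths.sum())
    variants: List[SiteVariant] = []
    seen = set()
    base_p = np.asarray(spec.base_composition)
    for ci in chrom_idx:
        chrom, length = spec.chromosomes[ci]
        pos = int(rng.integers(1, length + 1))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        ref = None
        if sequence_lookup is not None:
            ref = sequence_lookup(chrom, pos)
        if ref is None:
            ref = BASES[rng.choice(4, p=base_p)]
        row = enu.spectrum.get(ref)
        if row is None:  # spectrum may omit a base; fall back to uniform
            alts = [b for b in BASES if b != ref]
            alt = alts[rng.integers(3)]
        else:
            alts = list(row)
            alt = alts[rng.choice(len(alts), p=np.array([row[a] for a in alts]))]
        variants.append(SiteVariant(chrom, pos, ref, alt, kind="enu"))
    variants.sort(key=lambda v: (v.chromosome, v.position))
    return variants


def uniform_maf(low: float = 0.1, high: float = 0.5) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Factory for a uniform minor-allele-frequency sampler."""

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(low, high, size=n)

    return sample


def place_markers(
    spec: GenomeSpec,
    n_markers: int,
    maf_sampler: Callable[[np.random.Generator, int], np.ndarray],
    rng: np.random.Generator,
) -> List[dict]:
    """Place array markers uniformly over the genome with sampled MAFs.

    Returns row dicts (chrom, pos, name, ref/alt allele letters, maf); the
    two allele letters are arbitrary distinct bases, ``ref`` being the
    major allele by construction.
    """
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    lengths = np.array([length for _, length in spec.chromosomes], dtype=float)
    chrom_idx = rng.choice(len(lengths), size=n_markers, p=lengths / lengths.sum())
    mafs = maf_sampler(rng, n_markers)
    rows = []
    seen = set()
    k = 0
    for i, ci in enumerate(chrom_idx):
        chrom, length = spec.chromosomes[ci]
        pos = int(rng.integers(1, length + 1))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        a1i, a2i = rng.choice(4, size=2, replace=False)
        k += 1
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "kind": "marker",
                "name": f"snp{k:06d}",
                "ref": BASES[a1i],
                "alt": BASES[a2i],
                "maf": float(min(mafs[i], 1.0 - mafs[i])),
            }
        )
    return rows


def build_site_map(
    spec: GenomeSpec,
    marker_rows: List[dict],
    variants: List[SiteVariant],
    causal: Optional[CausalPlant] = None,
) -> Tuple[SiteMap, Dict[str, int]]:
    """Assemble the global site map; returns it plus per-kind counts.

    Variant or marker rows colliding with the causal position are dropped
    in favour of the causal site.
    """
    rows: List[dict] = []
    for r in marker_rows:
        rows.append(dict(r))
    for i, v in enumerate(variants, start=1):
        rows.append(
            {
                "chrom": v.chromosome,
                "pos": v.position,
                "kind": v.kind,
                "name": f"{v.kind}{i:06d}",
                "ref": v.ref,
                "alt": v.alt,
                "maf": np.nan,
            }
        )
    if causal is not None:
        taken = {(r["chrom"], r["pos"]) for r in [
            {"chrom": causal.chromosome, "pos": causal.position}
        ]}
        rows = [r for r in rows if (r["chrom"], r["pos"]) not in taken]
        rows.append(
            {
                "chrom": causal.chromosome,
                "pos": causal.position,
                "kind": "causal",
                "name": "causal",
                "ref": causal.ref_allele,
                "alt": causal.alt_allele,
                "maf": np.nan,
            }
        )
    tables: Dict[str, pd.DataFrame] = {}
    for chrom, _ in spec.chromosomes:
        sub = [r for r in rows if r["chrom"] == chrom]
        tables[chrom] = pd.DataFrame(sub, columns=["chrom", *SITE_COLUMNS]).drop(
            columns="chrom"
        )
    counts = pd.DataFrame(rows)["kind"].value_counts().to_dict() if rows else {}
    return SiteMap(tables), counts
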