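"""Transmission disequilibrium test over a genotyped pedigree.

For every (heterozygous parent, affected offspring) pair with complete
genotypes, the minor allele is either transmitted (counts toward ``b``) or
not (``c``); the statistic is ``(b - c)^2 / (b + c)`` on one degree of
freedom.  When both parents are heterozygous and the offspring is too, the
individual transmissions cannot be resolved but their joint contribution
can: one transmitted plus one untransmitted minor allele from the two
parents together.

Transmissions are collected once into a matrix shared by the observed scan
and the permutation engine: entry ``S[m, p]`` is +1/-1 when transmission
unit ``p`` (a fixed parent-offspring pair) transmitted / did not transmit
the minor allele at marker ``m``, and 0 when that pair is uninformative
there.  The ambiguous double-het/het-offspring configuration is encoded as
a +1 and a -1 on the trio's two parental columns: the observed counts get
the joint one-transmitted/one-untransmitted resolution, while independent
sign flips of the two columns regenerate the correct {-2, 0, +2} null
distribution of the pair's net contribution (freezing it at zero would
underestimate the permutation variance and inflate the family-wise error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.stats import chi2 as chi2_dist

from enumap.io.plink import MISSING, GenotypeMatrix
from enumap.pedsim.pedigree import AFFECTED, Pedigree


@dataclass
class TransmissionSet:
    """Per-marker, per-pair transmission signs."""

    signs: np.ndarray  # (n_markers, n_pairs) int8 in {-1, 0, +1}
    pairs: List[Tuple[str, str]]  # (parent id, offspring id) per column

    @property
    def b(self) -> np.ndarray:
        return (self.signs == 1).sum(axis=1)

    @property
    def c(self) -> np.ndarray:
        return (self.signs == -1).sum(axis=1)

    @property
    def informative(self) -> np.ndarray:
        """b + c per marker."""
        return np.abs(self.signs).sum(axis=1)

    def chi2(self) -> np.ndarray:
        """Observed statistic per marker; NaN where b + c = 0."""
        d = self.signs.sum(axis=1).astype(float)
        n = self.informative.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, d * d / n, np.nan)


def collect_transmissions(
    pedigree: Pedigree, matrix: GenotypeMatrix
) -> TransmissionSet:
    """Enumerate minor-allele transmissions to affected offspring.

    Minor-allele orientation is determined per marker from the sample
    allele frequency (dosage allele ``a2`` when its frequency is <= 0.5,
    the other allele otherwise).  Trios with a Mendelian-impossible
    genotype configuration at a marker contribute nothing there.
    """
    trios = [
        (sire, dam, child)
        for sire, dam, child in pedigree.trios()
        if child.phenotype == AFFECTED
    ]
    pairs: List[Tuple[str, str]] = []
    for sire, dam, child in trios:
        pairs.append((sire.id, child.id))
        pairs.append((dam.id, child.id))
    n_markers = matrix.n_markers
    signs = np.zeros((n_markers, len(pairs)), dtype=np.int8)
    if not trios or n_markers == 0:
        return TransmissionSet(signs, pairs)

    af = matrix.allele_freq()
    # dosage of the *minor* allele: flip where a2 is the major allele
    flip = af > 0.5
    geno = matrix.geno

    for t_idx, (sire, dam, child) in enumerate(trios):
        jf = matrix.sample_index(sire.id)
        jm = matrix.sample_index(dam.id)
        jc = matrix.sample_index(child.id)
        gf = geno[:, jf].astype(np.int16)
        gm = geno[:, jm].astype(np.int16)
        gc = geno[:, jc].astype(np.int16)
        ok = (gf != MISSING) & (gm != MISSING) & (gc != MISSING)
        f = np.where(flip, 2 - gf, gf)
        m = np.where(flip, 2 - gm, gm)
        c = np.where(flip, 2 - gc, gc)

        col_f = 2 * t_idx
        col_m = 2 * t_idx + 1

        both_het = ok & (f == 1) & (m == 1)
        # double heterozygous parents: offspring genotype resolves either
        # both transmissions (hom offspring) or only their joint total
        signs[both_het & (c == 2), col_f] = 1
        signs[both_het & (c == 2), col_m] = 1
        signs[both_het & (c == 0), col_f] = -1
        signs[both_het & (c == 0), col_m] = -1
        # ambiguous joint resolution: one transmitted + one untransmitted
        signs[both_het & (c == 1), col_f] = 1
        signs[both_het & (c == 1), col_m] = -1

        # exactly one parent heterozygous: the homozygous parent's
        # contribution is forced, so the het parent's transmission is
        # offspring dosage minus that forced allele
        for het_col, g_het, g_hom in ((col_f, f, m), (col_m, m, f)):
            one_het = ok & (g_het == 1) & (g_hom != 1)
            forced = g_hom // 2  # 0 or 1 copies of the minor allele
            t = c - forced
            valid = one_het & ((t == 0) | (t == 1))
            signs[valid & (t == 1), het_col] = 1
            signs[valid & (t == 0), het_col] = -1
    return TransmissionSet(signs, pairs)


def tdt_counts(pedigree: Pedigree, matrix: GenotypeMatrix, marker: str) -> Tuple[int, int]:
    """(b, c) minor-allele transmission counts for one marker."""
    idx = matrix.markers.index[matrix.markers["name"] == marker]
    if len(idx) == 0:
        raise KeyError(f"marker {marker!r} not in matrix")
    ts = collect_transmissions(pedigree, matrix)
    i = int(idx[0])
    return int(ts.b[i]), int(ts.c[i])


def tdt_statistic(b: int, c: int) -> Tuple[float, float]:
    """(chi2, nominal p) for transmission counts; (nan, nan) when b+c=0."""
    if b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    n = b + c
    if n == 0:
        return (float("nan"), float("nan"))
    stat = (b - c) ** 2 / n
    return (float(stat), float(chi2_dist.sf(stat, 1)))
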