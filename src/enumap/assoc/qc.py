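"""Marker quality control: call rate, minor allele frequency, HWE.

Markers failing any criterion are removed in a fixed order — call rate,
then MAF, then Hardy–Weinberg — and the per-step removal counts are
reported.  MAF and HWE are computed on founders by default (a pedigree is
a very non-random mating scheme); pass ``population="all"`` to use every
genotyped animal instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from enumap.io.plink import GenotypeMatrix
from enumap.pedsim.pedigree import Pedigree


@dataclass(frozen=True)
class QcThresholds:
    """Removal thresholds: a marker is dropped when its call rate or MAF is
    *below* the minimum, or its HWE exact p-value is below ``hwe_alpha``."""

    min_call_rate: float = 0.90
    min_maf: float = 0.05
    hwe_alpha: float = 1.0e-3

    def __post_init__(self) -> None:
        for name, v in (
            ("min_call_rate", self.min_call_rate),
            ("min_maf", self.min_maf),
            ("hwe_alpha", self.hwe_alpha),
        ):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Conditional exact Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count no more likely than the observed one (the
    standard two-sided exact formulation used by common GWAS toolkits).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_a = n_Aa + 2 * n_aa  # minor-allele count (orientation is irrelevant)
    n_A = 2 * n - n_a
    rare = min(n_A, n_a)
    # feasible heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr  # common homozygotes
    # log P(het = h | n, rare) up to a shared constant
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    observed = p[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, p[p <= observed * (1.0 + 1e-12)].sum()))


def qc_filter(
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    thresholds: QcThresholds = QcThresholds(),
    population: str = "founders",
) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the three QC criteria in order; return (filtered matrix, report).

    The report has one row per step (``call_rate``, ``maf``, ``hwe``) with
    the number of markers entering, removed and retained.
    """
    if matrix.n_markers == 0:
        raise ValueError("empty genotype matrix")
    if population == "founders":
        pop: Optional[List[str]] = [f.id for f in pedigree.founders()]
    elif population == "all":
        pop = None
    else:
        raise ValueError("population must be 'founders' or 'all'")

    steps = []
    current = matrix

    cr = current.call_rate()
    keep = cr >= thresholds.min_call_rate
    steps.append(("call_rate", current.n_markers, int((~keep).sum())))
    current = current.subset_markers(keep)

    af = current.allele_freq(pop)
    maf = np.fmin(af, 1.0 - af)
    # NaN frequency (no calls in the QC population) also fails the step
    keep = ~(maf < thresholds.min_maf) & ~np.isnan(maf)
    steps.append(("maf", current.n_markers, int((~keep).sum())))
    current = current.subset_markers(keep)

    counts = current.genotype_counts(pop)
    pvals = np.array([
        hwe_exact_p(int(a), int(b), int(c)) if (a + b + c) > 0 else 1.0
        for a, b, c in counts
    ])
    keep = pvals >= thresholds.hwe_alpha
    steps.append(("hwe", current.n_markers, int((~keep).sum())))
    current = current.subset_markers(keep)

    report = pd.DataFrame(
        [
            {"step": name, "markers_in": n_in, "removed": removed, "retained": n_in - removed}
            for name, n_in, removed in steps
        ]
    )
    return current, report
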