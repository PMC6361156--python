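"""Family-wise corrected TDT p-values by max-statistic permutation.

Under the TDT null every informative transmission is an independent fair
coin, whatever the population structure, so the null is simulated by
flipping the transmitted/untransmitted label of each parent-offspring
transmission unit with probability one half.  A unit keeps the same flip
across all markers within a permutation, preserving the inter-marker
correlation that the max-statistic correction relies on.  The corrected
p-value of a marker is the add-one estimate
``(1 + #{permutations with max statistic >= observed}) / (n_perm + 1)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from enumap.assoc.tdt import TransmissionSet, collect_transmissions, tdt_statistic
from enumap.io.plink import GenotypeMatrix
from enumap.pedsim.pedigree import Pedigree
from scipy.stats import chi2 as chi2_dist


def permutation_maxT(
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    n_perm: int,
    seed_or_rng,
) -> pd.DataFrame:
    """Corrected per-marker TDT p-values; deterministic for a fixed seed.

    Returns a DataFrame with one row per marker: ``marker, chrom, pos, b,
    c, chi2, p_nominal, p_corrected``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    ts = collect_transmissions(pedigree, matrix)
    observed = ts.chi2()
    denom = ts.informative.astype(float)
    has_info = denom > 0

    n_pairs = ts.signs.shape[1]
    max_stats = np.zeros(n_perm)
    if n_pairs > 0 and has_info.any():
        S = ts.signs.astype(np.float64)
        # flip matrix: one sign per transmission unit per permutation
        flips = rng.choice(np.array([-1.0, 1.0]), size=(n_pairs, n_perm))
        D = S @ flips  # (n_markers, n_perm)
        with np.errstate(invalid="ignore", divide="ignore"):
            stats = np.where(has_info[:, None], D * D / denom[:, None], -np.inf)
        max_stats = stats.max(axis=0)

    p_corr = np.full(matrix.n_markers, np.nan)
    obs = np.where(has_info, observed, np.nan)
    for i in np.flatnonzero(has_info):
        p_corr[i] = (1.0 + (max_stats >= observed[i]).sum()) / (n_perm + 1.0)

    with np.errstate(invalid="ignore"):
        p_nom = chi2_dist.sf(observed, 1)
    return pd.DataFrame(
        {
            "marker": matrix.markers["name"].to_numpy(),
            "chrom": matrix.markers["chrom"].to_numpy(),
            "pos": matrix.markers["pos"].to_numpy(),
            "b": ts.b,
            "c": ts.c,
            "chi2": obs,
            "p_nominal": np.where(has_info, p_nom, np.nan),
            "p_corrected": p_corr,
        }
    )


def tdt_scan(matrix: GenotypeMatrix, pedigree: Pedigree) -> pd.DataFrame:
    """Uncorrected TDT scan (no permutations); same layout minus p_corrected."""
    ts = collect_transmissions(pedigree, matrix)
    rows = [tdt_statistic(int(b), int(c)) for b, c in zip(ts.b, ts.c)]
    chi2, p_nom = zip(*rows) if rows else ((), ())
    return pd.DataFrame(
        {
            "marker": matrix.markers["name"].to_numpy(),
            "chrom": matrix.markers["chrom"].to_numpy(),
            "pos": matrix.markers["pos"].to_numpy(),
            "b": ts.b,
            "c": ts.c,
            "chi2": np.array(chi2, dtype=float),
            "p_nominal": np.array(p_nom, dtype=float),
        }
    )
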