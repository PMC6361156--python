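"""From simulated truth to noisy SNP-array calls."""

from __future__ import annotations

import numpy as np
import pandas as pd

from enumap.pedsim.breed import TruthSet


def genotype_markers(
    truth: TruthSet,
    missing_rate: float,
    error_rate: float,
    seed_or_rng,
):
    """Extract array-marker genotypes from the truth set and add call noise.

    Each call is dropped (set missing) with probability ``missing_rate``;
    each *allele* of a surviving call is flipped with probability
    ``error_rate`` (so a genotype is perturbed with probability just under
    ``2 * error_rate``).  Marker ``a1``/``a2`` letters come from the site
    table; ``a2`` is the designated minor allele of the simulation.
    """
    # imported here to keep the io <-> pedsim dependency one-directional
    from enumap.io.plink import MISSING, GenotypeMatrix

    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    rows = []
    genos = []
    for chrom in truth.sites.chromosomes:
        table = truth.sites.tables[chrom]
        is_marker = (table["kind"] == "marker").to_numpy()
        if not is_marker.any():
            continue
        sub = table[is_marker]
        dose = truth.dosage(chrom)[is_marker]  # (n_markers, n_ind)
        if error_rate > 0:
            # per-haplotype flips on the underlying diplotypes
            idx = np.flatnonzero(is_marker)
            hap = truth.diplotypes[chrom][:, :, idx]  # (n_ind, 2, n_markers)
            flips = rng.random(hap.shape) < error_rate
            hap = np.where(flips, 1 - hap, hap)
            dose = hap.sum(axis=1).T.astype(np.int8)
        genos.append(dose)
        cm = sub["pos"].to_numpy() / 1e6 * truth.spec.recombination_rate
        rows.append(
            pd.DataFrame(
                {
                    "name": sub["name"].to_numpy(),
                    "chrom": chrom,
                    "pos": sub["pos"].to_numpy(),
                    "cm": cm,
                    "a1": sub["ref"].to_numpy(),
                    "a2": sub["alt"].to_numpy(),
                }
            )
        )
    if not rows:
        raise ValueError("truth set contains no markers")
    markers = pd.concat(rows, ignore_index=True)
    geno = np.concatenate(genos, axis=0).astype(np.int8)
    if missing_rate > 0:
        drop = rng.random(geno.shape) < missing_rate
        geno = np.where(drop, MISSING, geno).astype(np.int8)
    return GenotypeMatrix(geno, markers, truth.pedigree.ids)
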