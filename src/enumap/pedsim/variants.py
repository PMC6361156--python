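"""Exome variant emission and simulated control panels."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from enumap.io.vcfio import VcfRecord, write_vcf
from enumap.pedsim.breed import TruthSet

VARIANT_KINDS = ("enu", "shared", "causal")


def exome_records(
    truth: TruthSet,
    sequenced: Sequence[str],
    depth_mean: Optional[float] = None,
    qual_mean: float = 60.0,
    rng: Optional[np.random.Generator] = None,
) -> List[VcfRecord]:
    """Variant records carried by at least one sequenced individual.

    One record per ``enu``/``shared``/``causal`` site at which any
    sequenced individual has a non-reference allele; genotypes are reported
    for the sequenced individuals only (whole-exome calls, not the Sanger
    follow-up).  Optional per-sample depths are Poisson(``depth_mean``).
    """
    for s in sequenced:
        if s not in truth.pedigree:
            raise KeyError(f"unknown individual {s!r}")
    cols = [truth.index_of_individual(s) for s in sequenced]
    records: List[VcfRecord] = []
    for chrom in truth.sites.chromosomes:
        table = truth.sites.tables[chrom]
        keep = table["kind"].isin(VARIANT_KINDS).to_numpy()
        if not keep.any():
            continue
        dose = truth.dosage(chrom)[keep][:, cols]  # (n_var, n_seq)
        sub = table[keep].reset_index(drop=True)
        carried = (dose > 0).any(axis=1)
        for i in np.flatnonzero(carried):
            genotypes = {s: int(dose[i, j]) for j, s in enumerate(sequenced)}
            depths: Dict[str, int] = {}
            qual = qual_mean
            if rng is not None:
                if depth_mean is not None:
                    depths = {s: int(rng.poisson(depth_mean)) for s in sequenced}
                qual = float(np.round(qual_mean + rng.normal(0, 5), 1))
            records.append(
                VcfRecord(
                    chrom=chrom,
                    pos=int(sub["pos"][i]),
                    ref=str(sub["ref"][i]),
                    alt=str(sub["alt"][i]),
                    qual=qual,
                    id=str(sub["name"][i]),
                    genotypes=genotypes,
                    depths=depths,
                )
            )
    return records


def emit_exome_vcf(
    truth: TruthSet,
    sequenced: Sequence[str],
    path: Path,
    depth_mean: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> Path:
    """Write the exome VCF for the sequenced individuals (header-only when
    the list is empty)."""
    records = exome_records(truth, sequenced, depth_mean=depth_mean, rng=rng)
    contigs = [(name, length) for name, length in truth.spec.chromosomes]
    return write_vcf(records, list(sequenced), contigs, path)


def control_panel_genotypes(
    truth: TruthSet,
    n_controls: int,
    rng: np.random.Generator,
    shared_freq_range=(0.05, 0.5),
) -> pd.DataFrame:
    """Simulate unrelated control animals typed at every exome variant site.

    ``shared`` strain polymorphisms segregate in controls at a per-site
    frequency drawn from ``shared_freq_range`` (at least one alt carrier is
    guaranteed so the site is genuinely non-novel); mutagen-induced and
    causal alleles are absent from controls by construction.

    Returns a DataFrame with columns chrom, pos, ref, alt, kind and one
    dosage column per control.
    """
    sites = truth.sites.sites_of_kind(*VARIANT_KINDS)
    out = sites[["chrom", "pos", "ref", "alt", "kind"]].copy()
    n_var = len(out)
    geno = np.zeros((n_var, n_controls), dtype=np.int8)
    shared = (out["kind"] == "shared").to_numpy()
    if shared.any() and n_controls > 0:
        freq = rng.uniform(*shared_freq_range, size=int(shared.sum()))
        draws = (
            (rng.random((int(shared.sum()), n_controls)) < freq[:, None]).astype(np.int8)
            + (rng.random((int(shared.sum()), n_controls)) < freq[:, None]).astype(np.int8)
        )
        # guarantee the panel actually carries the allele
        none = draws.sum(axis=1) == 0
        draws[none, 0] = 1
        geno[shared] = draws
    for j in range(n_controls):
        out[f"ctrl{j + 1:03d}"] = geno[:, j]
    return out


def write_truth_table(truth: TruthSet, path: Path) -> Path:
    """Full truth table: every site, kind, alleles and per-individual dosage."""
    frames = []
    for chrom in truth.sites.chromosomes:
        table = truth.sites.tables[chrom].copy()
        table.insert(0, "chrom", chrom)
        dose = truth.dosage(chrom)
        for j, ind_id in enumerate(truth.pedigree.ids):
            table[ind_id] = dose[:, j]
        frames.append(table)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return path
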