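"""PED/MAP text genotypes and the in-memory genotype matrix.

The dialect is the classic whitespace-delimited PED/MAP pair: a MAP file
with ``chrom  marker  cM  bp`` per marker, and a PED file with six leading
columns (family, individual, sire, dam, sex, phenotype) followed by two
allele letters per marker; ``0`` encodes a missing allele, sires/dams of
founders are ``0``, sex is 1/2 (male/female) and phenotype 1/2/0
(unaffected/affected/unknown).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from enumap.pedsim.pedigree import (
    AFFECTED,
    FEMALE,
    Individual,
    MALE,
    Pedigree,
    UNAFFECTED,
    UNKNOWN,
)

MISSING = np.int8(-1)

_SEX_OUT = {MALE: "1", FEMALE: "2"}
_SEX_IN = {"1": MALE, "2": FEMALE}
_PHEN_OUT = {UNAFFECTED: "1", AFFECTED: "2", UNKNOWN: "0"}
_PHEN_IN = {"1": UNAFFECTED, "2": AFFECTED, "0": UNKNOWN, "-9": UNKNOWN}


class GenotypeMatrix:
    """Biallelic genotype calls, markers x individuals.

    Attributes
    ----------
    geno:
        ``int8`` array of shape (n_markers, n_individuals): dosage of the
        ``a2`` allele (0, 1 or 2), ``-1`` for a missing call.
    markers:
        DataFrame with columns ``name, chrom, pos, cm, a1, a2``.
    samples:
        Individual ids, column order of ``geno``.
    """

    def __init__(self, geno: np.ndarray, markers: pd.DataFrame, samples: List[str]):
        geno = np.asarray(geno, dtype=np.int8)
        if geno.ndim != 2:
            raise ValueError("geno must be 2-D (markers x individuals)")
        if geno.shape[0] != len(markers):
            raise ValueError("marker table does not match geno rows")
        if geno.shape[1] != len(samples):
            raise ValueError("sample list does not match geno columns")
        self.geno = geno
        self.markers = markers.reset_index(drop=True)
        self.samples = list(samples)
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_markers(self) -> int:
        return self.geno.shape[0]

    @property
    def n_samples(self) -> int:
        return self.geno.shape[1]

    def sample_index(self, ind_id: str) -> int:
        return self._sample_index[ind_id]

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return (self.geno != MISSING).mean(axis=1)

    def allele_freq(self, sample_ids: Optional[List[str]] = None) -> np.ndarray:
        """Per-marker frequency of the ``a2`` allele (NaN if no calls)."""
        g = self.geno
        if sample_ids is not None:
            cols = [self._sample_index[s] for s in sample_ids]
            g = g[:, cols]
        called = g != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(called, g, 0).sum(axis=1) / (2.0 * called.sum(axis=1))

    def genotype_counts(self, sample_ids: Optional[List[str]] = None) -> np.ndarray:
        """Per-marker (n_hom_a1, n_het, n_hom_a2) counts."""
        g = self.geno
        if sample_ids is not None:
            cols = [self._sample_index[s] for s in sample_ids]
            g = g[:, cols]
        out = np.stack([(g == k).sum(axis=1) for k in (0, 1, 2)], axis=1)
        return out

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.geno[keep], self.markers.loc[keep], self.samples)

    def row(self, marker_name: str) -> np.ndarray:
        idx = self.markers.index[self.markers["name"] == marker_name]
        if len(idx) == 0:
            raise KeyError(f"marker {marker_name!r} not in matrix")
        return self.geno[idx[0]]


def write_ped_map(
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    prefix: Path,
) -> Tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns the two paths."""
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    m = matrix.markers
    with open(map_path, "w") as fh:
        for row in m.itertuples():
            fh.write(f"{row.chrom}\t{row.name}\t{row.cm:.6f}\t{row.pos}\n")
    a1 = m["a1"].to_numpy()
    a2 = m["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for ind in pedigree.individuals:
            j = matrix.sample_index(ind.id)
            fields = [
                pedigree.families.get(ind.id, "0"),
                ind.id,
                ind.sire or "0",
                ind.dam or "0",
                _SEX_OUT[ind.sex],
                _PHEN_OUT[ind.phenotype],
            ]
            g = matrix.geno[:, j]
            alleles = np.empty((matrix.n_markers, 2), dtype=object)
            for k in range(matrix.n_markers):
                d = g[k]
                if d == MISSING:
                    alleles[k] = ("0", "0")
                elif d == 0:
                    alleles[k] = (a1[k], a1[k])
                elif d == 1:
                    alleles[k] = (a1[k], a2[k])
                else:
                    alleles[k] = (a2[k], a2[k])
            fields.extend(a for pair in alleles for a in pair)
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_ped_map(ped_path: Path, map_path: Path) -> Tuple[GenotypeMatrix, Pedigree]:
    """Read a PED/MAP pair back into a matrix and pedigree.

    Allele orientation: ``a2`` is the minor (less frequent) allele in the
    file; ties broken alphabetically.  Generations are not recorded in PED
    and come back as ``None``.
    """
    markers = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "name", "cm", "pos"],
        dtype={"chrom": str, "name": str, "cm": float, "pos": int},
    )
    n_markers = len(markers)
    rows: List[List[str]] = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"PED row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele columns, expected {2 * n_markers}"
                )
            rows.append(parts)

    inds: List[Individual] = []
    families: Dict[str, str] = {}
    for parts in rows:
        fam, iid, sire, dam, sex, phen = parts[:6]
        inds.append(
            Individual(
                id=iid,
                sire=None if sire == "0" else sire,
                dam=None if dam == "0" else dam,
                sex=_SEX_IN.get(sex, MALE),
                generation=None,
                phenotype=_PHEN_IN.get(phen, UNKNOWN),
            )
        )
        families[iid] = fam
    pedigree = Pedigree(inds, families=families)

    n_ind = len(rows)
    allele = np.empty((n_markers, n_ind, 2), dtype="U1")
    for j, parts in enumerate(rows):
        body = parts[6:]
        allele[:, j, 0] = body[0::2]
        allele[:, j, 1] = body[1::2]

    geno = np.full((n_markers, n_ind), MISSING, dtype=np.int8)
    a1_out, a2_out = [], []
    for k in range(n_markers):
        flat = allele[k].ravel()
        called = flat != "0"
        letters, counts = np.unique(flat[called], return_counts=True)
        if len(letters) > 2:
            raise ValueError(f"marker {markers['name'][k]} is not biallelic")
        if len(letters) == 0:
            a1, a2 = "0", "0"
        elif len(letters) == 1:
            a1, a2 = letters[0], letters[0]
        else:
            order = np.lexsort((letters, -counts))  # major first, ties alphabetical
            a1, a2 = letters[order[0]], letters[order[1]]
        a1_out.append(a1)
        a2_out.append(a2)
        ok = (allele[k, :, 0] != "0") & (allele[k, :, 1] != "0")
        dose = (allele[k, :, 0] == a2).astype(np.int8) + (allele[k, :, 1] == a2).astype(np.int8)
        geno[k, ok] = dose[ok]
    markers["a1"] = a1_out
    markers["a2"] = a2_out
    markers = markers[["name", "chrom", "pos", "cm", "a1", "a2"]]
    matrix = GenotypeMatrix(geno, markers, [ind.id for ind in inds])
    return matrix, pedigree
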