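"""Coding-effect annotation of point variants against simple gene models.

Plus-strand models only: the simulated genome plants every gene on the
plus strand, and the annotation contract mirrors that.  Effects are
classified by codon comparison under the standard genetic code:

* ``synonymous`` / ``missense`` / ``nonsense`` for CDS substitutions,
* ``splice_site`` for intronic positions within 2 bp of an exon edge,
* ``non_coding`` for everything else (UTR, deep intron, intergenic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

from enumap.exome.models import FragmentStore, GeneModel
from enumap.splice.transcript import CODON_TABLE

SPLICE_WINDOW = 2  # bp of intron adjacent to each exon counted as splice site

#: Effects treated as "non-synonymous" by the candidate cascade.
DAMAGING_EFFECTS = ("missense", "nonsense", "splice_site")


@dataclass(frozen=True)
class Annotation:
    """Predicted effect of one substitution on one gene."""

    gene: Optional[str]
    effect: str  # synonymous | missense | nonsense | splice_site | non_coding
    cds_position: Optional[int] = None
    codon_index: Optional[int] = None
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None


def cds_pos_to_codon(cds_position: int) -> Tuple[int, int]:
    """Map a 1-based CDS coordinate to (codon index, offset in codon).

    Offsets are 1, 2 or 3; e.g. CDS position 1226 is base 2 of codon 409.
    """
    if cds_position < 1:
        raise ValueError("CDS positions are 1-based")
    return ((cds_position - 1) // 3 + 1, (cds_position - 1) % 3 + 1)


def _splice_site_gene(pos: int, gene: GeneModel) -> bool:
    for i in range(len(gene.exons) - 1):
        intron_start = gene.exons[i][1] + 1
        intron_end = gene.exons[i + 1][0] - 1
        if intron_start > intron_end:
            continue
        if intron_start <= pos <= min(intron_start + SPLICE_WINDOW - 1, intron_end):
            return True
        if max(intron_end - SPLICE_WINDOW + 1, intron_start) <= pos <= intron_end:
            return True
    return False


def annotate_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genes: Iterable[GeneModel],
    sequences: FragmentStore,
) -> Annotation:
    """Annotate a substitution; positions outside every gene are non-coding.

    The first gene whose span contains the position wins (the simulated
    annotation has no overlapping genes).  A reference-base mismatch
    against the fragment sequence raises ``ValueError``.
    """
    gene = next(
        (g for g in genes if g.chrom == chrom and g.contains(pos)), None
    )
    if gene is None:
        return Annotation(gene=None, effect="non_coding")
    if gene.strand != "+":
        raise NotImplementedError("only plus-strand gene models are supported")

    cds_pos = gene.cds_position_of(pos)
    if cds_pos is None:
        effect = "splice_site" if _splice_site_gene(pos, gene) else "non_coding"
        return Annotation(gene=gene.gene_id, effect=effect)

    observed = sequences.base_at(chrom, pos)
    if observed is not None and observed != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: sequence has {observed}, "
            f"variant claims {ref}"
        )
    codon_index, offset = cds_pos_to_codon(cds_pos)
    codon_start_cds = (codon_index - 1) * 3 + 1
    codon = "".join(
        sequences.get(chrom, p, p)
        for p in (
            gene.genomic_position_of_cds(codon_start_cds + k) for k in range(3)
        )
    )
    alt_codon = codon[: offset - 1] + alt.upper() + codon[offset:]
    aa_ref = CODON_TABLE[codon]
    aa_alt = CODON_TABLE[alt_codon]
    if aa_alt == aa_ref:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "nonsense"
    else:
        effect = "missense"
    aa_alt_label = "*" if aa_alt == "*" else aa_alt
    hgvs_p = (
        f"p.{aa_ref}{codon_index}="
        if effect == "synonymous"
        else f"p.{aa_ref}{codon_index}{aa_alt_label}"
    )
    return Annotation(
        gene=gene.gene_id,
        effect=effect,
        cds_position=cds_pos,
        codon_index=codon_index,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        hgvs_c=f"c.{cds_pos}{ref.upper()}>{alt.upper()}",
        hgvs_p=hgvs_p,
    )
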