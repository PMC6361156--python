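"""A deterministic multi-exon gene engineered to mirror the mapped mutation.

The fixture gene has twelve exons; exon 10 is 103 bp, CDS position 1226 is
the second base of codon 409 (``GAT``, Asp), and the local context spells
the enhancer motif ``G[A/G]TCTGAGG``.  Skipping exon 10 shifts the frame
(103 mod 3 = 1) and the downstream sequence is engineered so the shifted
frame terminates immediately, yielding a truncated protein.  RT-PCR
primers anchored in exons 9 and 11 give a 377 bp product on the full
transcript and 274 bp after the skip; the companion minigene model carries
91/103/164 bp insert segments on a vector contributing 169 bp.

Everything is generated from a fixed internal seed: the fixture is
byte-stable across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from enumap.exome.models import FragmentStore, GeneModel
from enumap.pedsim.genome import CausalPlant
from enumap.splice.minigene import MinigeneModel
from enumap.splice.pwm import WeightMatrix
from enumap.splice.transcript import (
    CODON_TABLE,
    Exon,
    PrimerPair,
    TranscriptModel,
)

GENE_ID = "geneX"

#: CDS bases contributed by each exon, 5' to 3'.  Exons 1-9 sum to 1200 so
#: that CDS 1226 falls 26 bp into the 103 bp exon 10; the total is 4608
#: (1535 codons plus the stop).
EXON_CDS_LENGTHS: Tuple[int, ...] = (150, 130, 140, 120, 135, 125, 145, 115, 140, 103, 160, 3145)

_FLANK = 300
_FIXTURE_SEED = 713

# engineered codons (1-based codon ordinal -> triplet):
#   1     start
#   409   GAT (Asp; base 2 is CDS 1226, the A>G site)
#   410/411 complete the G[A/G]TCTGAGG enhancer motif
#   435/436 place a TAA in the +1 frame right after the exon 9/11 junction,
#           so the exon-10 skip truncates the protein at 400 aa
#   1536  stop
_ENGINEERED = {1: "ATG", 409: "GAT", 410: "CTG", 411: "AGG", 435: "CTA", 436: "AAA", 1536: "TAA"}

_SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TABLE.items() if aa != "*"))


@dataclass(frozen=True)
class GeneFixture:
    """All artefacts of the engineered locus, ready for every stage."""

    gene: GeneModel
    transcript: TranscriptModel
    fragments: FragmentStore
    fragment_start: int
    plant: CausalPlant
    weight_matrix: WeightMatrix
    minigene: MinigeneModel
    primers: PrimerPair
    skipped_exon_id: str = "ex10"

    @property
    def cds(self) -> str:
        return self.transcript.spliced_seq


def fixture_weight_matrix() -> WeightMatrix:
    """An 8-wide test matrix whose consensus is the fixture motif with the
    mutant base preferred at position 2 (documented surrogate for a
    published splicing-factor matrix, which ships separately)."""
    consensus = "GGTCTGAG"
    order = "ACGT"
    scores = np.full((4, 8), -0.5)
    for i, base in enumerate(consensus):
        scores[order.index(base), i] = 0.6
    scores[order.index("G"), 1] = 0.85
    scores[order.index("A"), 1] = 0.50
    return WeightMatrix(name="testSR", scores=scores, threshold=2.0)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _build_cds(rng: np.random.Generator) -> str:
    n_codons = sum(EXON_CDS_LENGTHS) // 3
    codons = []
    picks = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    for ordinal in range(1, n_codons + 1):
        codons.append(_ENGINEERED.get(ordinal, _SENSE_CODONS[picks[ordinal - 1]]))
    return "".join(codons)


def make_duox2_like_fixture(
    chrom: str = "chr1",
    causal_position: int = 50_000_000,
) -> GeneFixture:
    """Build the engineered gene so the A>G site lands at ``causal_position``.

    Returns the gene model, transcript, genomic fragment, causal plant,
    fixture weight matrix, minigene model and RT-PCR primers.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    cds = _build_cds(rng)
    assert len(cds) == sum(EXON_CDS_LENGTHS)
    assert cds[1224:1233] == "GATCTGAGG", "enhancer motif must sit at CDS 1225-1233"

    # lay the gene out on a local fragment, 1-based from position 1
    pieces = []
    exon_intervals = []
    pos = 1
    upstream = _random_seq(rng, _FLANK)
    pieces.append(upstream)
    pos += _FLANK
    offset = 0
    for i, ex_len in enumerate(EXON_CDS_LENGTHS, start=1):
        exon_intervals.append((pos, pos + ex_len - 1))
        pieces.append(cds[offset : offset + ex_len])
        offset += ex_len
        pos += ex_len
        if i < len(EXON_CDS_LENGTHS):
            intron_len = 150 + 10 * i
            pieces.append("GT" + _random_seq(rng, intron_len - 4) + "AG")
            pos += intron_len
    pieces.append(_random_seq(rng, _FLANK))
    fragment_local = "".join(pieces)

    # genomic shift so that CDS position 1226 = causal_position
    local_gene = GeneModel(
        gene_id=GENE_ID,
        chrom=chrom,
        exons=tuple(exon_intervals),
        cds=tuple(exon_intervals),
    )
    local_causal = local_gene.genomic_position_of_cds(1226)
    shift = causal_position - local_causal
    fragment_start = 1 + shift
    if fragment_start < 1:
        raise ValueError("causal_position too close to the chromosome start")
    gene = GeneModel(
        gene_id=GENE_ID,
        chrom=chrom,
        exons=tuple((s + shift, e + shift) for s, e in exon_intervals),
        cds=tuple((s + shift, e + shift) for s, e in exon_intervals),
    )
    fragments = FragmentStore()
    fragments.add(chrom, fragment_start, fragment_local)

    transcript = TranscriptModel(
        gene_id=GENE_ID,
        exons=tuple(
            Exon(f"ex{i + 1}", s, e) for i, (s, e) in enumerate(gene.exons)
        ),
        spliced_seq=cds,
        cds_offset=0,
    )
    plant = CausalPlant(
        chromosome=chrom,
        position=causal_position,
        ref_allele="A",
        alt_allele="G",
        gene=GENE_ID,
        cds_position=1226,
        inheritance="recessive",
        penetrance=1.0,
    )
    # exon 9 contributes its last 137 bp, exon 11 its first 137 bp: 377 bp
    # full-length amplicon, 274 bp once the 103 bp exon 10 is skipped
    primers = PrimerPair(forward=("ex9", 4), reverse=("ex11", 137))
    minigene = MinigeneModel(
        vector_contribution=169,
        segments={"ex9": 91, "ex10": 103, "ex11": 164},
    )
    return GeneFixture(
        gene=gene,
        transcript=transcript,
        fragments=fragments,
        fragment_start=fragment_start,
        plant=plant,
        weight_matrix=fixture_weight_matrix(),
        minigene=minigene,
        primers=primers,
    )
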