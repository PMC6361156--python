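"""Transcript models, exon skipping, translation and amplicon arithmetic."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = ("TAA", "TAG", "TGA")


class SkipError(ValueError):
    """Raised when an exon cannot be skipped (missing or terminal)."""


class PrimerDropout(ValueError):
    """Raised when a primer anchor's exon is absent from the transcript."""


@dataclass(frozen=True)
class Exon:
    """An exon with genomic coordinates (1-based inclusive, plus strand)."""

    id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"exon {self.id}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exons plus the spliced sequence they produce.

    ``cds_offset`` is the 0-based offset of the first CDS base within the
    spliced sequence (0 when the transcript is pure CDS).
    """

    gene_id: str
    exons: Tuple[Exon, ...]
    spliced_seq: str
    cds_offset: int = 0

    def __post_init__(self) -> None:
        total = sum(e.length for e in self.exons)
        if total != len(self.spliced_seq):
            raise ValueError(
                f"exon lengths sum to {total} but spliced sequence is "
                f"{len(self.spliced_seq)} bp"
            )
        if not 0 <= self.cds_offset < max(len(self.spliced_seq), 1):
            raise ValueError("cds_offset outside spliced sequence")

    @property
    def exon_ids(self) -> List[str]:
        return [e.id for e in self.exons]

    def exon(self, exon_id: str) -> Exon:
        for e in self.exons:
            if e.id == exon_id:
                return e
        raise KeyError(exon_id)

    def exon_tx_start(self, exon_id: str) -> int:
        """1-based transcript coordinate of an exon's first base."""
        offset = 0
        for e in self.exons:
            if e.id == exon_id:
                return offset + 1
            offset += e.length
        raise KeyError(exon_id)

    @property
    def cds_seq(self) -> str:
        return self.spliced_seq[self.cds_offset :]


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer anchors as (exon id, 1-based offset in exon)."""

    forward: Tuple[str, int]
    reverse: Tuple[str, int]


@dataclass(frozen=True)
class IsoformConsequence:
    """Predicted outcome of skipping one internal exon."""

    skipped_exon: str
    skipped_length: int
    frameshift: bool
    premature_stop: bool
    stop_codon_index: Optional[int]  # codon ordinal in the mutant ORF
    protein_length: int  # aa, excluding the stop


def skip_exon(t: TranscriptModel, exon_id: str) -> TranscriptModel:
    """Remove one internal exon and its sequence from the transcript."""
    ids = t.exon_ids
    if exon_id not in ids:
        raise SkipError(f"no exon {exon_id!r} in transcript")
    if exon_id in (ids[0], ids[-1]):
        raise SkipError(f"exon {exon_id!r} is terminal; skipping is undefined")
    start = t.exon_tx_start(exon_id) - 1
    length = t.exon(exon_id).length
    new_seq = t.spliced_seq[:start] + t.spliced_seq[start + length :]
    new_exons = tuple(e for e in t.exons if e.id != exon_id)
    cds_offset = t.cds_offset
    if start < cds_offset:
        cds_offset = max(0, cds_offset - min(length, cds_offset - start))
    return TranscriptModel(
        gene_id=t.gene_id, exons=new_exons, spliced_seq=new_seq, cds_offset=cds_offset
    )


def translate_cds(cds: str) -> Tuple[str, bool, Optional[int]]:
    """Translate with the standard code, halting at the first stop.

    Returns ``(protein, stop_found, stop_codon_index)`` where the index is
    the 1-based codon ordinal of the stop.  Trailing bases short of a full
    codon are ignored.  Non-ACGT bases raise ``ValueError``.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    cds = cds.upper()
    protein = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        aa = CODON_TABLE.get(codon)
        if aa is None:
            raise ValueError(f"invalid codon {codon!r} at CDS position {i + 1}")
        if aa == "*":
            return "".join(protein), True, i // 3 + 1
        protein.append(aa)
    return "".join(protein), False, None


def consequence_of_skip(t: TranscriptModel, exon_id: str) -> IsoformConsequence:
    """Frameshift/premature-stop consequence of skipping ``exon_id``."""
    skipped_length = t.exon(exon_id).length
    mutant = skip_exon(t, exon_id)
    frameshift = skipped_length % 3 != 0
    wt_protein, _, _ = translate_cds(t.cds_seq)
    protein, stop_found, stop_idx = translate_cds(mutant.cds_seq)
    premature = stop_found and len(protein) < len(wt_protein)
    return IsoformConsequence(
        skipped_exon=exon_id,
        skipped_length=skipped_length,
        frameshift=frameshift,
        premature_stop=premature,
        stop_codon_index=stop_idx,
        protein_length=len(protein),
    )


def amplicon_length(t: TranscriptModel, primers: PrimerPair) -> int:
    """Spliced-transcript length between the two primer anchors, inclusive.

    Raises :class:`PrimerDropout` when an anchor's exon is not in the
    transcript (the skipped-exon primer dropout seen on a gel).
    """
    for exon_id, offset in (primers.forward, primers.reverse):
        if exon_id not in t.exon_ids:
            raise PrimerDropout(f"anchor exon {exon_id!r} absent from transcript")
        if not 1 <= offset <= t.exon(exon_id).length:
            raise ValueError(f"offset {offset} outside exon {exon_id!r}")
    fwd = t.exon_tx_start(primers.forward[0]) + primers.forward[1] - 1
    rev = t.exon_tx_start(primers.reverse[0]) + primers.reverse[1] - 1
    if rev < fwd:
        raise ValueError("reverse anchor precedes forward anchor")
    return rev - fwd + 1
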