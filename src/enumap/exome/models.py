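"""Gene models and genomic sequence fragments."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene on the plus strand of a simulated genome.

    Coordinates are 1-based inclusive.  ``exons`` and ``cds`` are ordered
    (start, end) interval lists; for the simple single-exon genes the two
    coincide.
    """

    gene_id: str
    chrom: str
    exons: Tuple[Tuple[int, int], ...]
    cds: Tuple[Tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        for intervals in (self.exons, self.cds):
            last_end = 0
            for start, end in intervals:
                if start > end:
                    raise ValueError(f"{self.gene_id}: interval {start}-{end} inverted")
                if start <= last_end:
                    raise ValueError(f"{self.gene_id}: intervals overlap or unsorted")
                last_end = end
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def cds_position_of(self, pos: int) -> Optional[int]:
        """1-based CDS coordinate of a genomic position, or None."""
        offset = 0
        for start, end in self.cds:
            if start <= pos <= end:
                return offset + (pos - start) + 1
            offset += end - start + 1
        return None

    def genomic_position_of_cds(self, cds_pos: int) -> int:
        """Inverse of :meth:`cds_position_of`."""
        if cds_pos < 1 or cds_pos > self.cds_length:
            raise ValueError(f"CDS position {cds_pos} outside CDS")
        remaining = cds_pos - 1
        for start, end in self.cds:
            seg = end - start + 1
            if remaining < seg:
                return start + remaining
            remaining -= seg
        raise AssertionError("unreachable")


class FragmentStore:
    """Genomic sequence available only as fragments around genes.

    A full chromosome-scale reference is never materialised; sequence is
    stored per fragment keyed by chromosome, with 1-based inclusive
    genomic coordinates.
    """

    def __init__(self) -> None:
        self._fragments: Dict[str, List[Tuple[int, int, str]]] = {}

    def add(self, chrom: str, start: int, seq: str) -> None:
        end = start + len(seq) - 1
        self._fragments.setdefault(chrom, []).append((start, end, seq.upper()))
        self._fragments[chrom].sort()

    def fragments(self) -> Dict[str, List[Tuple[int, int, str]]]:
        return self._fragments

    def base_at(self, chrom: str, pos: int) -> Optional[str]:
        for start, end, seq in self._fragments.get(chrom, []):
            if start <= pos <= end:
                return seq[pos - start]
        return None

    def get(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end]; the range must lie in one fragment."""
        for fs, fe, seq in self._fragments.get(chrom, []):
            if fs <= start and end <= fe:
                return seq[start - fs : end - fs + 1]
        raise KeyError(f"{chrom}:{start}-{end} not covered by any fragment")

    def cds_sequence(self, gene: GeneModel) -> str:
        return "".join(self.get(gene.chrom, s, e) for s, e in gene.cds)
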