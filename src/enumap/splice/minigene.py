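"""Minigene RT-PCR product arithmetic.

A minigene construct contributes a fixed number of vector-derived bases to
every RT-PCR product (the plasmid exon trap arms amplified by the
vector-specific primers); each insert segment that is retained in the
mature transcript adds its own length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence


@dataclass(frozen=True)
class MinigeneModel:
    """Vector contribution plus named insert segments with their lengths."""

    vector_contribution: int
    segments: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vector_contribution <= 0:
            raise ValueError("vector_contribution must be positive")
        for name, length in self.segments.items():
            if length <= 0:
                raise ValueError(f"segment {name!r} has non-positive length")


def minigene_products(
    m: MinigeneModel, patterns: Sequence[Iterable[str]]
) -> List[int]:
    """Product length for each inclusion pattern.

    Each pattern is an iterable of segment ids retained in the product;
    its length is the vector contribution plus the sum of the included
    segment lengths.  Unknown segment ids raise ``KeyError``.
    """
    lengths = []
    for pattern in patterns:
        total = m.vector_contribution
        for seg in pattern:
            if seg not in m.segments:
                raise KeyError(f"unknown segment {seg!r}")
            total += m.segments[seg]
        lengths.append(total)
    return lengths
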