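"""Target-region coverage summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np


@dataclass(frozen=True)
class CoverageConfig:
    """Depth threshold and capture-target intervals (1-based inclusive)."""

    min_depth: int = 20
    targets: Tuple[Tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def normalize_intervals(
    intervals: List[Tuple[str, int, int]]
) -> List[Tuple[str, int, int]]:
    """Sort and merge overlapping or bookended intervals per chromosome."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end < start:
            raise ValueError(f"inverted interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    out: List[Tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        merged: List[List[int]] = []
        for start, end in sorted(by_chrom[chrom]):
            if merged and start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        out.extend((chrom, s, e) for s, e in merged)
    return out


def coverage_summary(
    depths: Dict[Tuple[str, int, int], np.ndarray],
    cfg: CoverageConfig,
) -> Tuple[float, np.ndarray]:
    """Fraction of target bases at depth >= ``cfg.min_depth`` plus histogram.

    ``depths`` maps each target interval (chrom, start, end; 1-based
    inclusive) to its per-base integer depth track.  The histogram counts
    bases by depth and sums to the total target length.
    """
    if not depths:
        raise ValueError("empty target set")
    tracks = []
    for (chrom, start, end), track in depths.items():
        track = np.asarray(track, dtype=np.int64)
        if len(track) != end - start + 1:
            raise ValueError(
                f"depth track for {chrom}:{start}-{end} has {len(track)} bases, "
                f"expected {end - start + 1}"
            )
        if (track < 0).any():
            raise ValueError("negative depth")
        tracks.append(track)
    alldepths = np.concatenate(tracks)
    frac = float((alldepths >= cfg.min_depth).mean())
    histogram = np.bincount(alldepths)
    return frac, histogram
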