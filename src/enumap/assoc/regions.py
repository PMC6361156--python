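"""Calling significant genomic regions from corrected TDT results."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List

import pandas as pd


@dataclass(frozen=True)
class RegionCall:
    """A run of significant markers on one chromosome (1-based inclusive)."""

    chromosome: str
    start: int
    end: int
    n_significant_markers: int
    peak_marker: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.n_significant_markers < 1:
            raise ValueError("a region must contain at least one significant marker")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chromosome and self.start <= pos <= self.end


def call_significant_region(
    results: pd.DataFrame,
    alpha: float = 0.05,
    merge_gap_bp: int = 10_000_000,
    p_column: str = "p_corrected",
) -> List[RegionCall]:
    """Merge significant markers (``p < alpha``) into regions per chromosome.

    Adjacent significant markers are merged while their gap is at most
    ``merge_gap_bp``; region bounds are the outermost significant markers
    and the peak is the marker with the largest statistic.  Returns an
    empty list when nothing is significant.
    """
    required = {"marker", "chrom", "pos", "chi2", p_column}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results missing columns: {sorted(missing)}")
    sig = results[results[p_column] < alpha].sort_values(["chrom", "pos"])
    regions: List[RegionCall] = []
    for chrom, group in sig.groupby("chrom", sort=True):
        block: List[pd.Series] = []
        prev_pos = None
        for _, row in group.iterrows():
            if prev_pos is not None and row["pos"] - prev_pos > merge_gap_bp:
                regions.append(_close_block(chrom, block))
                block = []
            block.append(row)
            prev_pos = row["pos"]
        if block:
            regions.append(_close_block(chrom, block))
    regions.sort(key=lambda r: (r.chromosome, r.start))
    return regions


def _close_block(chrom: str, block: List[pd.Series]) -> RegionCall:
    peak = max(block, key=lambda r: r["chi2"])
    return RegionCall(
        chromosome=str(chrom),
        start=int(block[0]["pos"]),
        end=int(block[-1]["pos"]),
        n_significant_markers=len(block),
        peak_marker=str(peak["marker"]),
    )


def write_regions_bed(regions: List[RegionCall], path: Path) -> Path:
    """Write regions as BED (0-based half-open, as the format requires)."""
    lines = [
        f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.peak_marker}\t{r.n_significant_markers}"
        for r in regions
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return Path(path)


def parse_region(text: str) -> RegionCall:
    """Parse ``chrom:start-end`` (1-based inclusive) into a region."""
    chrom, _, span = text.partition(":")
    start_s, _, end_s = span.partition("-")
    try:
        start, end = int(start_s.replace(",", "")), int(end_s.replace(",", ""))
    except ValueError as exc:
        raise ValueError(f"cannot parse region {text!r}") from exc
    return RegionCall(
        chromosome=chrom, start=start, end=end, n_significant_markers=1, peak_marker="."
    )
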