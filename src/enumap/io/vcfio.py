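"""Minimal VCF v4.2 writing and pysam-backed reading.

Written records carry a GT-only FORMAT (optionally GT:DP when per-sample
depths are supplied); the writer is fully deterministic — no timestamps or
environment-dependent header lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pysam


@dataclass
class VcfRecord:
    """One biallelic site with per-sample dosages of the alt allele."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: Optional[float] = None
    id: str = "."
    genotypes: Dict[str, int] = field(default_factory=dict)  # id -> 0/1/2, -1 missing
    depths: Dict[str, int] = field(default_factory=dict)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_GT_IN = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def write_vcf(
    records: Sequence[VcfRecord],
    samples: Sequence[str],
    contigs: Sequence[Tuple[str, int]],
    path: Path,
) -> Path:
    """Write sorted records for ``samples`` to ``path`` (uncompressed text)."""
    path = Path(path)
    with_depth = any(r.depths for r in records)
    fmt = "GT:DP" if with_depth else "GT"
    lines = ["##fileformat=VCFv4.2", "##source=enumap"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if with_depth:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header_cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        header_cols += "\tFORMAT\t" + "\t".join(samples)
    lines.append(header_cols)
    order = {name: i for i, (name, _) in enumerate(contigs)}
    for rec in sorted(records, key=lambda r: (order.get(r.chrom, 1 << 30), r.pos)):
        qual = "." if rec.qual is None else f"{rec.qual:g}"
        line = f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}\t{qual}\tPASS\t."
        if samples:
            cells = []
            for s in samples:
                gt = _GT[rec.genotypes.get(s, -1)]
                if with_depth:
                    dp = rec.depths.get(s)
                    cells.append(f"{gt}:{dp if dp is not None else '.'}")
                else:
                    cells.append(gt)
            line += f"\t{fmt}\t" + "\t".join(cells)
        lines.append(line)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path: Path) -> Tuple[List[VcfRecord], List[str]]:
    """Read a VCF into records, splitting multi-allelic sites on ingest.

    For a split allele, sample dosage counts copies of that allele only;
    any other non-reference allele is treated as reference.
    """
    records: List[VcfRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for site in vf:
            alts = site.alts or ()
            for ai, alt in enumerate(alts, start=1):
                genotypes: Dict[str, int] = {}
                depths: Dict[str, int] = {}
                for s in samples:
                    call = site.samples[s]
                    gt = call.get("GT")
                    if gt is None or any(a is None for a in gt):
                        genotypes[s] = -1
                    else:
                        genotypes[s] = sum(1 for a in gt if a == ai)
                    dp = call.get("DP")
                    if dp is not None:
                        depths[s] = int(dp)
                records.append(
                    VcfRecord(
                        chrom=site.chrom,
                        pos=site.pos,
                        ref=site.ref,
                        alt=alt,
                        qual=site.qual,
                        id=site.id or ".",
                        genotypes=genotypes,
                        depths=depths,
                    )
                )
    return records, samples
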