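"""GFF3 writing (gene/mRNA/exon/CDS) and reading for simulated gene models."""

from __future__ import annotations

from pathlib import Path
from typing import List

from enumap.exome.models import GeneModel


def write_gff3(genes: List[GeneModel], path: Path) -> Path:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        base = f"{g.chrom}\tenumap"
        lines.append(
            f"{base}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        mrna = f"{g.gene_id}.t1"
        lines.append(
            f"{base}\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={mrna};Parent={g.gene_id}"
        )
        for i, (s, e) in enumerate(g.exons, start=1):
            lines.append(
                f"{base}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna}.exon{i};Parent={mrna}"
            )
        phase = 0
        for i, (s, e) in enumerate(g.cds, start=1):
            lines.append(
                f"{base}\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                f"ID={mrna}.cds{i};Parent={mrna}"
            )
            phase = (3 - ((e - s + 1 - phase) % 3)) % 3
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def read_gff3(path: Path) -> List[GeneModel]:
    """Parse gene models written by :func:`write_gff3` (or compatible GFF3).

    Exon and CDS features are attached to genes via their ``Parent`` chain;
    one transcript per gene is assumed.
    """
    genes: dict = {}
    mrna_to_gene: dict = {}
    exons: dict = {}
    cds: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            continue
        chrom, _, ftype, start, end, _, strand, _, attrs = parts
        fields = dict(
            kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
        )
        if ftype == "gene":
            genes[fields["ID"]] = {"chrom": chrom, "strand": strand}
        elif ftype == "mRNA":
            mrna_to_gene[fields["ID"]] = fields["Parent"]
        elif ftype in ("exon", "CDS"):
            gene_id = mrna_to_gene.get(fields["Parent"], fields["Parent"])
            store = exons if ftype == "exon" else cds
            store.setdefault(gene_id, []).append((int(start), int(end)))
    out = []
    for gene_id, meta in genes.items():
        out.append(
            GeneModel(
                gene_id=gene_id,
                chrom=meta["chrom"],
                strand=meta["strand"],
                exons=tuple(sorted(exons.get(gene_id, []))),
                cds=tuple(sorted(cds.get(gene_id, []))),
            )
        )
    return out
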