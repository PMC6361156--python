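"""FASTA round-trip for genome fragments.

Fragment records use headers of the form ``>chrom:start-end`` with 1-based
inclusive coordinates, so a handful of gene loci can stand in for a genome
that is never materialised in full.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from enumap.exome.models import FragmentStore


def write_fragments(store: FragmentStore, path: Path) -> Path:
    records = []
    for chrom, frags in sorted(store.fragments().items()):
        for start, end, seq in frags:
            records.append(
                SeqRecord(Seq(seq), id=f"{chrom}:{start}-{end}", description="")
            )
    SeqIO.write(records, str(path), "fasta")
    return Path(path)


def read_fragments(path: Path) -> FragmentStore:
    store = FragmentStore()
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        try:
            chrom, span = name.rsplit(":", 1)
            start, _ = span.split("-")
            store.add(chrom, int(start), str(record.seq))
        except ValueError:
            # plain record id: treat as a whole sequence starting at 1
            store.add(name, 1, str(record.seq))
    return store
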