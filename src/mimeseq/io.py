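"""File-format helpers: FASTA, FASTQ, GFF3 and the spike-in panel TSV.

GFF3 features use miRBase-style types (``miRNA_primary_transcript`` for
pre-miRNA hairpins, ``miRNA`` for mature sequences) with 1-based inclusive
coordinates on disk; in memory everything is 0-based half-open.
"""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mapping import Annotation

_GFF_TYPE = {"pre_mirna": "miRNA_primary_transcript", "mature": "miRNA"}
_GFF_KIND = {v: k for k, v in _GFF_TYPE.items()}


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality) from a strict 4-line FASTQ(.gz).

    Malformed records raise ValueError naming the record index.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        i = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            plus = fh.readline()
            qual = fh.readline().strip()
            if (not header.startswith("@") or not plus.startswith("+")
                    or not seq or len(seq) != len(qual)):
                raise ValueError(f"malformed FASTQ record {i} in {path}")
            yield header[1:].split()[0], seq.upper(), qual
            i += 1


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        chunk: list[str] = []
        for name, seq, qual in records:
            chunk.append(f"@{name}\n{seq}\n+\n{qual}\n")
            if len(chunk) >= 20000:
                fh.write("".join(chunk))
                chunk.clear()
        fh.write("".join(chunk))


def read_gff3(path: str | Path) -> list[Annotation]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in _GFF_KIND:
            continue
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        out.append(Annotation(
            contig=feat.seqid, kind=_GFF_KIND[feat.featuretype], name=name,
            start=feat.start - 1, end=feat.end, strand=feat.strand,
        ))
    return out


def write_gff3(annotations: Iterable[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write(
                f"{a.contig}\t.\t{_GFF_TYPE[a.kind]}\t{a.start + 1}\t{a.end}\t."
                f"\t{a.strand}\t.\tID={a.name};Name={a.name}\n"
            )
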