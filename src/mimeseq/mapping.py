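"""miRNA transcriptome construction and exact-prefix read mapping.

The transcriptome is built by excising every pre-miRNA interval (plus an
optional flank) from the genome; intervals that overlap after flanking are
merged into a single contig carrying all of their annotations, and coordinates
are lifted accordingly.

Mapping follows Tailor's core semantics: the longest prefix of the insert that
occurs exactly (no mismatches or indels) anywhere on either strand of the
indexed contigs is aligned; any remaining 3' suffix is reported as a
non-templated tail. All positions achieving the maximal prefix length are
reported and their number is the alignment multiplicity NH.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Annotation:
    """A pre-miRNA or mature feature; 0-based half-open internal coordinates."""

    contig: str
    kind: str  # "pre_mirna" | "mature"
    name: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval for {self.name}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand for {self.name}")


@dataclass(frozen=True)
class ReadAlignment:
    """Exact-prefix placement of an insert; the tail is the unmatched suffix."""

    insert_id: str
    contig: str
    strand: str
    start: int
    end: int
    prefix_len: int
    tail: str
    nh: int


def build_transcriptome(
    genome: Mapping[str, str],
    annotations: Iterable[Annotation],
    flank: int = 0,
) -> tuple[dict[str, str], list[Annotation]]:
    """Extract pre-miRNA contigs (± flank), merging overlapping annotations.

    Returns (contig sequences, annotations lifted to contig coordinates).
    Contigs are named ``chrom:start-end`` with 1-based inclusive coordinates.
    """
    annotations = list(annotations)
    pres = [a for a in annotations if a.kind == "pre_mirna"]
    for a in pres:
        if a.contig not in genome:
            raise ValueError(f"annotation {a.name} on unknown sequence {a.contig}")
        if a.end > len(genome[a.contig]):
            raise ValueError(f"annotation {a.name} beyond end of {a.contig}")
    windows: list[list] = []  # [chrom, start, end]
    for a in sorted(pres, key=lambda a: (a.contig, a.start)):
        lo = max(0, a.start - flank)
        hi = min(len(genome[a.contig]), a.end + flank)
        if windows and windows[-1][0] == a.contig and lo <= windows[-1][2]:
            windows[-1][2] = max(windows[-1][2], hi)
        else:
            windows.append([a.contig, lo, hi])

    contigs: dict[str, str] = {}
    lifted: list[Annotation] = []
    for chrom, lo, hi in windows:
        name = f"{chrom}:{lo + 1}-{hi}"
        contigs[name] = genome[chrom][lo:hi]
        for a in annotations:
            if a.contig == chrom and a.start >= lo and a.end <= hi:
                lifted.append(Annotation(name, a.kind, a.name,
                                         a.start - lo, a.end - lo, a.strand))
    return contigs, lifted


class PrefixIndex:
    """Seed-and-extend index over both strands supporting longest-exact-prefix lookup."""

    def __init__(self, contigs: Mapping[str, str], seed_len: int = 18):
        if not contigs:
            raise ValueError("no contigs to index")
        self.seed_len = seed_len
        self.contigs = dict(contigs)
        self._oriented: dict[tuple[str, str], str] = {}
        self._seeds: dict[str, list[tuple[str, str, int]]] = {}
        for cid, seq in self.contigs.items():
            seq = seq.upper()
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                self._oriented[(cid, strand)] = s
                for pos in range(len(s) - seed_len + 1):
                    kmer = s[pos: pos + seed_len]
                    if "N" in kmer:
                        continue
                    self._seeds.setdefault(kmer, []).append((cid, strand, pos))


def build_index(contigs: Mapping[str, str], seed_len: int = 18) -> PrefixIndex:
    return PrefixIndex(contigs, seed_len)


def map_insert(insert: str, index: PrefixIndex, min_prefix: int = 18,
               insert_id: str | None = None) -> list[ReadAlignment]:
    """Map an insert by its longest exact prefix; [] means unmapped.

    Reports every placement achieving the maximal prefix length; the suffix
    beyond the matched prefix is the non-templated tail.
    """
    if min_prefix < index.seed_len:
        raise ValueError("min_prefix shorter than the index seed length")
    iid = insert_id if insert_id is not None else insert
    if len(insert) < min_prefix:
        return []
    seed = insert[: index.seed_len]
    cands = index._seeds.get(seed, ())
    if not cands:
        return []
    best_len = 0
    best: list[tuple[str, str, int]] = []
    for cid, strand, pos in cands:
        s = index._oriented[(cid, strand)]
        ln = index.seed_len
        limit = min(len(insert), len(s) - pos)
        while ln < limit and insert[ln] == s[pos + ln]:
            ln += 1
        if ln > best_len:
            best_len, best = ln, [(cid, strand, pos)]
        elif ln == best_len:
            best.append((cid, strand, pos))
    if best_len < min_prefix:
        return []
    nh = len(best)
    out = []
    for cid, strand, pos in sorted(best):
        n = len(index._oriented[(cid, strand)])
        if strand == "+":
            start, end = pos, pos + best_len
        else:
            start, end = n - (pos + best_len), n - pos
        out.append(ReadAlignment(iid, cid, strand, start, end,
                                 best_len, insert[best_len:], nh))
    return out


def map_inserts(inserts: Iterable[str], index: PrefixIndex,
                min_prefix: int = 18) -> dict[str, list[ReadAlignment]]:
    """Map unique insert sequences; keys are the insert sequences themselves."""
    return {ins: map_insert(ins, index, min_prefix) for ins in set(inserts)}


def write_alignments_tsv(alignments: Iterable[ReadAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("insert_id\tcontig\tstrand\tstart\tend\ttail\tNH\n")
        for a in alignments:
            fh.write(f"{a.insert_id}\t{a.contig}\t{a.strand}\t{a.start}\t{a.end}"
                     f"\t{a.tail}\t{a.nh}\n")


def write_sam(alignments: Iterable[ReadAlignment], contigs: Mapping[str, str],
              path: str | Path) -> None:
    """Minimal SAM emission; the 3' tail is encoded as a soft clip."""
    alignments = list(alignments)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for cid, seq in contigs.items():
            fh.write(f"@SQ\tSN:{cid}\tLN:{len(seq)}\n")
        for a in alignments:
            flag = 0 if a.strand == "+" else 16
            cigar = f"{a.prefix_len}M"
            if a.tail:
                cigar += f"{len(a.tail)}S"
            seq = a.insert_id  # insert ids are the insert sequences in this pipeline
            if a.strand == "-":
                seq = revcomp(seq)
                cigar = (f"{len(a.tail)}S" if a.tail else "") + f"{a.prefix_len}M"
            fh.write(f"{a.insert_id}\t{flag}\t{a.contig}\t{a.start + 1}\t255\t{cigar}"
                     f"\t*\t0\t0\t{seq}\t*\tNH:i:{a.nh}\n")
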