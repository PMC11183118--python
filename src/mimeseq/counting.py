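"""Counting rules: windowed mature assignment, pre-miRNA overlap, tail tabulation.

A mapped insert counts toward a mature miRNA only when, on the same strand, its
templated (strand-aware) 5' end lies within ±tol5 of the annotated mature 5'
end and its templated 3' end does not exceed the annotated 3' end by more than
tol3 nucleotides; non-templated tails are excluded from these coordinates.
IsomiRs therefore sum into their parent mature miRNA. Multimapping inserts
contribute 1/NH per qualifying placement. Pre-miRNA counting is plain
strand-specific overlap (≥1 nt).
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .mapping import Annotation, ReadAlignment


def _five_prime_distance(aln: ReadAlignment, mat: Annotation) -> int:
    if aln.strand == "+":
        return abs(aln.start - mat.start)
    return abs(aln.end - mat.end)


def _qualifies(aln: ReadAlignment, mat: Annotation, tol5: int, tol3: int) -> bool:
    if aln.contig != mat.contig or aln.strand != mat.strand:
        return False
    if aln.strand == "+":
        return (abs(aln.start - mat.start) <= tol5
                and aln.end <= mat.end + tol3)
    return (abs(aln.end - mat.end) <= tol5
            and aln.start >= mat.start - tol3)


def assign_mature(aln: ReadAlignment, matures: Iterable[Annotation],
                  tol5: int = 5, tol3: int = 5) -> Annotation | None:
    """The single mature feature an alignment counts toward, if any.

    When several matures qualify (possible on merged contigs), the one with the
    nearest 5' end wins; ties break by lowest start coordinate, then by name.
    """
    best = None
    best_key = None
    for mat in matures:
        if not _qualifies(aln, mat, tol5, tol3):
            continue
        key = (_five_prime_distance(aln, mat), mat.start, mat.name)
        if best_key is None or key < best_key:
            best, best_key = mat, key
    return best


def _matures_by_contig(annotations: Iterable[Annotation]) -> dict[str, list[Annotation]]:
    by: dict[str, list[Annotation]] = {}
    for a in annotations:
        if a.kind == "mature":
            by.setdefault(a.contig, []).append(a)
    return by


def count_mature(alignments: Iterable[ReadAlignment],
                 annotations: Iterable[Annotation],
                 tol5: int = 5, tol3: int = 5,
                 weights: Mapping[str, float] | None = None) -> pd.Series:
    """Weighted (1/NH) mature counts; every annotated mature appears (0 allowed).

    ``weights`` maps insert_id to the number of reads carrying that insert
    (default 1), so unique insert sequences can be counted once and multiplied.
    """
    annotations = list(annotations)
    by_contig = _matures_by_contig(annotations)
    counts = {a.name: 0.0 for a in annotations if a.kind == "mature"}
    for aln in alignments:
        mat = assign_mature(aln, by_contig.get(aln.contig, ()), tol5, tol3)
        if mat is None:
            continue
        w = weights.get(aln.insert_id, 1.0) if weights is not None else 1.0
        counts[mat.name] += w / aln.nh
    return pd.Series(counts, name="count", dtype=float).sort_index()


def count_premirna(alignments: Iterable[ReadAlignment],
                   annotations: Iterable[Annotation],
                   weights: Mapping[str, float] | None = None) -> pd.Series:
    """1/NH-weighted counts of strand-specific overlaps (≥1 nt) per pre-miRNA."""
    pres = [a for a in annotations if a.kind == "pre_mirna"]
    counts = {a.name: 0.0 for a in pres}
    for aln in alignments:
        w = weights.get(aln.insert_id, 1.0) if weights is not None else 1.0
        for pre in pres:
            if (pre.contig == aln.contig and pre.strand == aln.strand
                    and aln.start < pre.end and pre.start < aln.end):
                counts[pre.name] += w / aln.nh
    return pd.Series(counts, name="count", dtype=float).sort_index()


def tabulate_tails(alignments: Iterable[ReadAlignment],
                   annotations: Iterable[Annotation],
                   tol5: int = 5, tol3: int = 5,
                   weights: Mapping[str, float] | None = None) -> pd.Series:
    """Unweighted read counts per (mature feature, tail sequence).

    The empty tail is the untailed bin. NH weighting is deliberately not
    applied; tails are descriptive per-feature statistics.
    """
    by_contig = _matures_by_contig(annotations)
    counts: dict[tuple[str, str], float] = {}
    for aln in alignments:
        mat = assign_mature(aln, by_contig.get(aln.contig, ()), tol5, tol3)
        if mat is None:
            continue
        w = weights.get(aln.insert_id, 1.0) if weights is not None else 1.0
        key = (mat.name, aln.tail)
        counts[key] = counts.get(key, 0.0) + w
    idx = pd.MultiIndex.from_tuples(counts.keys() or [("", "")],
                                    names=["feature", "tail"])
    return pd.Series(list(counts.values()) or [0.0], index=idx,
                     name="count").sort_index()


def counts_to_tsv(mature: pd.Series, premirna: pd.Series, path: str | Path) -> None:
    rows = [("mature", k, v) for k, v in mature.items()]
    rows += [("pre_mirna", k, v) for k, v in premirna.items()]
    pd.DataFrame(rows, columns=["kind", "feature", "raw_weighted_count"]).to_csv(
        path, sep="\t", index=False)
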