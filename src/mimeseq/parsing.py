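"""Raw-read decomposition: adapter alignment, barcode/UMI extraction, filtering.

Each read is decomposed by aligning the expected 3' adapter with an end-gap-free
("semiglobal") affine-gap alignment: matches +1, mismatches -1, gap open -2, gap
extension -1, terminal gaps free on both sequences. The alignment score is
normalized by the adapter length and reads below a minimum normalized score are
discarded as ``no_adapter``. The 11 nt immediately 5' of the adapter are the
UMI (6 nt, inner) and sample barcode (sRBC, 5 nt, adapter-adjacent); everything
further 5' is the small RNA insert. Inserts are then head-trimmed, quality
filtered, and length filtered, mirroring a default fastp pass.

The filter taxonomy is a partition: every read receives exactly one status of
``ok | no_adapter | wrong_srbc | too_short | low_quality``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import io
from .layout import DEFAULT_ADAPTER, HEAD_PAD, SRBC_LEN, UMI_LEN

STATUSES = ("ok", "no_adapter", "wrong_srbc", "too_short", "low_quality")

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGTN"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

_NEG = np.int32(-(10 ** 6))


@dataclass(frozen=True)
class ParseParams:
    """Scoring and filtering parameters for read decomposition."""

    adapter: str = DEFAULT_ADAPTER
    match_score: int = 1
    mismatch_score: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    min_norm_score: float = 0.9
    srbc_len: int = SRBC_LEN
    umi_len: int = UMI_LEN
    head_trim: int = HEAD_PAD
    min_len: int = 18
    # fastp-default-equivalent quality rule
    qual_floor: int = 15
    max_low_qual_frac: float = 0.4
    max_n: int = 5
    # if True the UMI (not the sRBC) is adjacent to the adapter
    srbc_inner: bool = False

    def __post_init__(self):
        if not (0 < self.min_norm_score <= 1):
            raise ValueError("min_norm_score must be in (0, 1]")
        if min(self.srbc_len, self.umi_len, self.head_trim, self.min_len) < 0:
            raise ValueError("lengths must be non-negative")
        if set(self.adapter) - set("ACGT"):
            raise ValueError("adapter must be over {A,C,G,T}")


@dataclass(frozen=True)
class AdapterHit:
    """Placement of the adapter on a read: 0-based half-open [start, end)."""

    start: int
    end: int
    raw_score: int
    norm_score: float


@dataclass
class ParsedRead:
    insert: str
    insert_qual: str
    umi: str
    srbc: str
    adapter_hit: AdapterHit
    status: str


@dataclass
class ParseStats:
    total: int = 0
    counts: dict = field(default_factory=lambda: {s: 0 for s in STATUSES})

    @property
    def fraction_surviving(self) -> float:
        return self.counts["ok"] / self.total if self.total else 0.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("status\tcount\n")
            for s in STATUSES:
                fh.write(f"{s}\t{self.counts[s]}\n")
            fh.write(f"total\t{self.total}\n")


def _encode(seqs: Sequence[str], length: int) -> np.ndarray:
    buf = "".join(seqs)
    codes = _CODE[np.frombuffer(buf.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = np.flatnonzero(codes < 0)[0]
        raise ValueError(f"non-ACGTN character {buf[bad]!r} in read sequence")
    return codes.reshape(len(seqs), length)


def _lexi_update(s, st, s2, st2):
    """Combine (score, start) pairs preferring higher score, then smaller start."""
    take = (s2 > s) | ((s2 == s) & (st2 < st))
    return np.where(take, s2, s), np.where(take, st2, st)


def _semiglobal_batch(reads: np.ndarray, adapter: np.ndarray, p: ParseParams):
    """End-gap-free affine DP of the adapter against a batch of equal-length reads.

    Returns (score, start, end) arrays; placement ties are broken by smallest
    start, then smallest end.
    """
    k, n = reads.shape
    m = len(adapter)
    go, ge = np.int32(p.gap_open), np.int32(p.gap_extend)
    H = np.zeros((k, m + 1), dtype=np.int32)
    SH = np.zeros((k, m + 1), dtype=np.int32)
    E = np.full((k, m + 1), _NEG, dtype=np.int32)
    SE = np.zeros((k, m + 1), dtype=np.int32)

    best_s = np.zeros(k, dtype=np.int32)       # empty alignment, score 0
    best_st = np.zeros(k, dtype=np.int32)
    best_en = np.zeros(k, dtype=np.int32)

    for i in range(1, n + 1):
        cand1, cand2 = H + go, E + ge
        take = (cand1 > cand2) | ((cand1 == cand2) & (SH < SE))
        En = np.where(take, cand1, cand2)
        SEn = np.where(take, SH, SE)

        Hn = np.empty_like(H)
        SHn = np.empty_like(SH)
        Hn[:, 0] = 0
        SHn[:, 0] = i
        F = np.full(k, _NEG, dtype=np.int32)
        SF = np.zeros(k, dtype=np.int32)
        col = reads[:, i - 1]
        for j in range(1, m + 1):
            sub = np.where(col == adapter[j - 1], p.match_score, p.mismatch_score)
            s, st = H[:, j - 1] + sub, SH[:, j - 1]
            f1, f2 = Hn[:, j - 1] + go, F + ge
            takeF = (f1 > f2) | ((f1 == f2) & (SHn[:, j - 1] < SF))
            F = np.where(takeF, f1, f2)
            SF = np.where(takeF, SHn[:, j - 1], SF)
            s, st = _lexi_update(s, st, En[:, j], SEn[:, j])
            s, st = _lexi_update(s, st, F, SF)
            Hn[:, j], SHn[:, j] = s, st
        H, SH, E, SE = Hn, SHn, En, SEn

        take = (H[:, m] > best_s) | ((H[:, m] == best_s) & (SH[:, m] < best_st))
        best_s = np.where(take, H[:, m], best_s)
        best_st = np.where(take, SH[:, m], best_st)
        best_en = np.where(take, i, best_en)

    for j in range(m):  # adapter truncated at the read 3' end (free end gap)
        take = (H[:, j] > best_s) | ((H[:, j] == best_s) & (SH[:, j] < best_st))
        best_s = np.where(take, H[:, j], best_s)
        best_st = np.where(take, SH[:, j], best_st)
        best_en = np.where(take, n, best_en)
    return best_s, best_st, best_en


def align_adapter(read: str, params: ParseParams | None = None) -> AdapterHit:
    """Best end-gap-free placement of the adapter on one read."""
    p = params or ParseParams()
    if not read:
        raise ValueError("empty read")
    reads = _encode([read], len(read))
    adapter = _CODE[np.frombuffer(p.adapter.encode(), dtype=np.uint8)]
    s, st, en = _semiglobal_batch(reads, adapter, p)
    m = len(p.adapter)
    return AdapterHit(int(st[0]), int(en[0]), int(s[0]), float(s[0]) / m)


def _align_many(seqs: list[str], p: ParseParams) -> list[AdapterHit]:
    """Adapter placement for many reads: exact-match fast path, batch DP fallback.

    An exact adapter occurrence achieves the maximum possible score with the
    leftmost placement, so it coincides with the DP optimum under the
    tie-breaking rules.
    """
    m = len(p.adapter)
    hits: list[AdapterHit | None] = [None] * len(seqs)
    todo: dict[int, list[int]] = {}
    full = 1.0 * p.match_score
    for idx, seq in enumerate(seqs):
        pos = seq.find(p.adapter)
        if pos >= 0:
            hits[idx] = AdapterHit(pos, pos + m, m * p.match_score, full)
        else:
            todo.setdefault(len(seq), []).append(idx)
    adapter = _CODE[np.frombuffer(p.adapter.encode(), dtype=np.uint8)]
    for length, idxs in todo.items():
        if length == 0:
            raise ValueError("empty read")
        mat = _encode([seqs[i] for i in idxs], length)
        s, st, en = _semiglobal_batch(mat, adapter, p)
        for row, i in enumerate(idxs):
            hits[i] = AdapterHit(int(st[row]), int(en[row]), int(s[row]),
                                 float(s[row]) / m)
    return hits  # type: ignore[return-value]


def _classify(seq: str, qual: str | None, hit: AdapterHit, expected_srbc: str,
              p: ParseParams) -> ParsedRead:
    empty = ParsedRead("", "", "", "", hit, "no_adapter")
    if hit.norm_score < p.min_norm_score:
        return empty
    tag_len = p.umi_len + p.srbc_len
    upstream = seq[: hit.start]
    if len(upstream) < tag_len:
        return empty  # insufficient bases upstream of the adapter
    if p.srbc_inner:
        umi = upstream[-p.umi_len:]
        srbc = upstream[-tag_len: -p.umi_len]
    else:
        srbc = upstream[-p.srbc_len:]
        umi = upstream[-tag_len: -p.srbc_len]
    insert_raw = upstream[: -tag_len]
    qual_raw = (qual or "I" * len(seq))[: len(insert_raw)]
    if srbc != expected_srbc:
        return ParsedRead("", "", umi, srbc, hit, "wrong_srbc")
    if len(insert_raw) < p.min_len:
        return ParsedRead(insert_raw, qual_raw, umi, srbc, hit, "too_short")
    insert = insert_raw[p.head_trim:]
    iqual = qual_raw[p.head_trim:]
    if insert:
        floor_char = chr(33 + p.qual_floor)
        if iqual and min(iqual) < floor_char:  # cheap screen before counting
            low = sum(1 for c in iqual if c < floor_char)
            if low / len(insert) > p.max_low_qual_frac:
                return ParsedRead(insert, iqual, umi, srbc, hit, "low_quality")
        if insert.count("N") > p.max_n:
            return ParsedRead(insert, iqual, umi, srbc, hit, "low_quality")
    if len(insert) < p.min_len:
        return ParsedRead(insert, iqual, umi, srbc, hit, "too_short")
    return ParsedRead(insert, iqual, umi, srbc, hit, "ok")


def parse_read(seq: str, expected_srbc: str, params: ParseParams | None = None,
               qual: str | None = None) -> ParsedRead:
    """Decompose one raw read into insert, UMI and sRBC (or a filter reason)."""
    p = params or ParseParams()
    if len(expected_srbc) != p.srbc_len:
        raise ValueError(f"expected sRBC must be {p.srbc_len} nt")
    return _classify(seq, qual, align_adapter(seq, p), expected_srbc, p)


def parse_records(records: Iterable[tuple[str, str, str]], expected_srbc: str,
                  params: ParseParams | None = None):
    """Parse (name, seq, qual) records; returns (stats, parsed list)."""
    p = params or ParseParams()
    if len(expected_srbc) != p.srbc_len:
        raise ValueError(f"expected sRBC must be {p.srbc_len} nt")
    recs = list(records)
    hits = _align_many([seq for _, seq, _ in recs], p)
    stats = ParseStats(total=len(recs))
    parsed = []
    for (name, seq, qual), hit in zip(recs, hits):
        pr = _classify(seq, qual, hit, expected_srbc, p)
        stats.counts[pr.status] += 1
        parsed.append((name, pr))
    return stats, parsed


def parse_fastq(path: str | Path, expected_srbc: str,
                params: ParseParams | None = None,
                out_fastq: str | Path | None = None,
                stats_path: str | Path | None = None):
    """Parse a FASTQ(.gz) library; returns (ParseStats, surviving records).

    Surviving records are (name, insert, insert_qual, umi) tuples; when
    ``out_fastq`` is given they are also written as FASTQ with the UMI and
    sRBC recorded in the header comment.
    """
    stats, parsed = parse_records(io.read_fastq(path), expected_srbc, params)
    survivors = [(name, pr.insert, pr.insert_qual, pr.umi)
                 for name, pr in parsed if pr.status == "ok"]
    if out_fastq is not None:
        io.write_fastq(
            ((f"{name} umi={umi} srbc={expected_srbc}", ins, q)
             for name, ins, q, umi in survivors), out_fastq)
    if stats_path is not None:
        stats.to_tsv(stats_path)
    return stats, survivors
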