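"""Adapter alignment and read decomposition."""
import numpy as np
import pytest
from Bio import Align

from mimeseq.layout import DEFAULT_ADAPTER
from mimeseq.parsing import (ParseParams, align_adapter, parse_fastq,
                             parse_read, parse_records)

from oracles import semiglobal_oracle

ADAPTER = DEFAULT_ADAPTER
P = ParseParams()


def _random_read(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _mutated_adapter(rng, n_ops):
    ad = list(ADAPTER)
    for _ in range(n_ops):
        op = rng.integers(0, 3)
        pos = int(rng.integers(0, len(ad)))
        if op == 0:
            ad[pos] = "ACGT"[rng.integers(0, 4)]
        elif op == 1:
            ad.insert(pos, "ACGT"[rng.integers(0, 4)])
        elif len(ad) > 1:
            del ad[pos]
    return "".join(ad)


def test_verbatim_adapter_identity_placement():
    read = "TTTT" + ADAPTER + "GGGCC"
    hit = align_adapter(read)
    assert (hit.start, hit.end) == (4, 4 + len(ADAPTER))
    assert hit.raw_score == len(ADAPTER)
    assert hit.norm_score == 1.0


def test_single_substitution_stays_above_cutoff():
    mutated = "C" + ADAPTER[1:] if ADAPTER[0] != "C" else "A" + ADAPTER[1:]
    hit = align_adapter("ACGT" + mutated + "TT")
    assert hit.raw_score == len(ADAPTER) - 2  # 20 matches - 1 mismatch
    assert hit.norm_score == pytest.approx(19 / 21)
    assert hit.norm_score >= 0.9


def test_truncated_adapter_free_end_gap():
    # adapter runs off the 3' end of the read; missing suffix costs nothing
    read = "ACGTACGTAC" + ADAPTER[:15]
    hit = align_adapter(read)
    assert hit.raw_score == 15
    assert (hit.start, hit.end) == (10, 25)


def test_n_treated_as_mismatch():
    read = ADAPTER.replace(ADAPTER[5], "N", 1)
    read = ADAPTER[:5] + "N" + ADAPTER[6:]
    hit = align_adapter(read)
    assert hit.raw_score == len(ADAPTER) - 2


def test_non_acgtn_rejected():
    with pytest.raises(ValueError):
        align_adapter("ACGTXACGT")
    with pytest.raises(ValueError):
        align_adapter("")


def test_aligner_matches_scalar_oracle_randomized():
    rng = np.random.default_rng(42)
    for _ in range(300):
        n = int(rng.integers(22, 70))
        read = _random_read(rng, n)
        if rng.random() < 0.7:
            ad = _mutated_adapter(rng, int(rng.integers(0, 4)))
            pos = int(rng.integers(0, max(1, n - len(ad))))
            read = (read[:pos] + ad + read[pos + len(ad):])[:n]
        hit = align_adapter(read)
        assert (hit.raw_score, hit.start, hit.end) == semiglobal_oracle(read, ADAPTER)


def test_aligner_score_matches_biopython():
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score, aligner.mismatch_score = 1, -1
    aligner.open_gap_score, aligner.extend_gap_score = -2, -1
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    rng = np.random.default_rng(7)
    for _ in range(100):
        read = _random_read(rng, int(rng.integers(25, 60)))
        if rng.random() < 0.5:
            read = read[:5] + _mutated_adapter(rng, 2) + read[5:]
        assert align_adapter(read).raw_score == aligner.score(read, ADAPTER)


def _build_read(insert, umi="TTTTTT", srbc="CGATC", head="ACGT",
                adapter=ADAPTER):
    return head + insert + umi + srbc + adapter


def test_parse_read_recovers_layout():
    insert = "A" * 18
    pr = parse_read(_build_read(insert), "CGATC")
    assert pr.status == "ok"
    assert pr.insert == insert
    assert pr.umi == "TTTTTT"
    assert pr.srbc == "CGATC"


def test_parse_read_wrong_srbc_single_mismatch():
    pr = parse_read(_build_read("A" * 18, srbc="CGATG"), "CGATC")
    assert pr.status == "wrong_srbc"


def test_parse_read_too_short():
    # 17-nt insert after the 4-nt head trim
    pr = parse_read(_build_read("A" * 17), "CGATC")
    assert pr.status == "too_short"


def test_parse_read_low_quality():
    read = _build_read("A" * 18)
    qual = "#" * len(read)  # Q2 everywhere
    pr = parse_read(read, "CGATC", qual=qual)
    assert pr.status == "low_quality"


def test_parse_read_no_adapter_on_random_sequence():
    rng = np.random.default_rng(3)
    read = _random_read(rng, 30)
    score, _, _ = semiglobal_oracle(read, ADAPTER)
    assert score / len(ADAPTER) < 0.9  # oracle confirms for this seed
    assert parse_read(read, "CGATC").status == "no_adapter"


def test_parse_read_insufficient_upstream_is_no_adapter():
    # passing adapter score but < 11 nt upstream of it
    pr = parse_read("ACGTT" + ADAPTER, "CGATC")
    assert pr.status == "no_adapter"


def test_srbc_inner_layout_swap():
    p = ParseParams(srbc_inner=True)
    read = "ACGT" + "A" * 18 + "CGATC" + "TTTTTT" + ADAPTER
    pr = parse_read(read, "CGATC", params=p)
    assert pr.status == "ok"
    assert pr.srbc == "CGATC" and pr.umi == "TTTTTT"


def test_filter_taxonomy_is_a_partition():
    rng = np.random.default_rng(11)
    recs = []
    for i in range(200):
        kind = i % 4
        if kind == 0:
            recs.append((f"r{i}", _build_read("A" * 18), "I" * 54))
        elif kind == 1:
            recs.append((f"r{i}", _build_read("C" * 18, srbc="AAAAA"), "I" * 54))
        elif kind == 2:
            recs.append((f"r{i}", _random_read(rng, 40), "I" * 40))
        else:
            recs.append((f"r{i}", _build_read("G" * 12), "I" * 48))
    stats, parsed = parse_records(recs, "CGATC")
    assert sum(stats.counts.values()) == stats.total == 200
    assert len(parsed) == 200
    assert stats.counts["wrong_srbc"] == 50
    assert stats.counts["too_short"] == 50


def test_lowering_min_norm_score_never_decreases_ok():
    rng = np.random.default_rng(5)
    recs = []
    for i in range(150):
        ad = _mutated_adapter(rng, int(rng.integers(0, 3)))
        recs.append((f"r{i}", "ACGT" + _random_read(rng, 18) + "TTTTTT"
                     + "CGATC" + ad, None))
    recs = [(n, s, "I" * len(s)) for n, s, _ in recs]
    previous = None
    for cutoff in (0.95, 0.9, 0.8, 0.5):
        stats, _ = parse_records(recs, "CGATC",
                                 ParseParams(min_norm_score=cutoff))
        if previous is not None:
            assert stats.counts["ok"] >= previous
        previous = stats.counts["ok"]


def test_parse_fastq_empty_file(tmp_path):
    fq = tmp_path / "empty.fastq"
    fq.write_text("")
    stats, survivors = parse_fastq(fq, "CGATC")
    assert stats.total == 0 and survivors == []


def test_parse_fastq_gzip_roundtrip(tmp_path):
    from mimeseq import io as mio
    fq = tmp_path / "lib.fastq.gz"
    read = _build_read("A" * 18)
    mio.write_fastq([("r0", read, "I" * len(read))], fq)
    stats, survivors = parse_fastq(fq, "CGATC")
    assert stats.counts["ok"] == 1
    assert survivors[0][1] == "A" * 18


def test_parse_fastq_malformed_record_names_index(tmp_path):
    fq = tmp_path / "bad.fastq"
    fq.write_text("@r0\nACGT\n+\nIIII\nnot-a-header\nACGT\n+\nIIII\n")
    with pytest.raises(ValueError, match="record"):
        parse_fastq(fq, "CGATC")
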