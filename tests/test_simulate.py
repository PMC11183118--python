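"""Synthetic assay generator: references, profiles, libraries, invariants."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mimeseq import (SimConfig, build_index, draw_mirnome,
                     make_reference, map_insert, parse_records,
                     simulate_library, simulate_profiles)
from mimeseq.mapping import revcomp
from mimeseq.simulate import expected_ox_unox


def test_reference_single_mirna_mature_is_substring(small_reference):
    ref = make_reference(SimConfig(seed=1, n_mirnas=1))
    pres = [a for a in ref.annotations if a.kind == "pre_mirna"]
    assert len(ref.contigs) == 1 and len(pres) == 1
    mat = next(a for a in ref.annotations if a.kind == "mature")
    contig = ref.contigs[mat.contig]
    sub = contig[mat.start:mat.end]
    oriented = ref.mature_oriented(mat.name)
    assert oriented in (sub, revcomp(sub))
    assert mat.start >= pres[0].start and mat.end <= pres[0].end


def test_reference_is_deterministic(tmp_path):
    cfg = SimConfig(seed=33, n_mirnas=5)
    for sub in ("a", "b"):
        d = tmp_path / sub
        d.mkdir()
        make_reference(cfg).write(d / "r.fa", d / "r.gff3")
    assert (tmp_path / "a/r.fa").read_bytes() == (tmp_path / "b/r.fa").read_bytes()
    assert (tmp_path / "a/r.gff3").read_bytes() == (tmp_path / "b/r.gff3").read_bytes()


def test_family_duplication_yields_nh2():
    cfg = SimConfig(seed=2, n_mirnas=4, n_families=1)
    ref = make_reference(cfg)
    mature = ref.mature_oriented("mir-1")
    dup = ref.mature_oriented("mir-1-P2")
    assert mature == dup
    index = build_index(ref.contigs)
    alns = map_insert(mature, index)
    assert len(alns) == 2 and all(a.nh == 2 for a in alns)


def test_profiles_kinetics_limits(small_config, small_mirnome):
    t0 = simulate_profiles(small_config, small_mirnome, timepoint=0.0)
    assert (t0.mirnas["meth_frac"] == 0.0).all()
    tinf = simulate_profiles(small_config, small_mirnome, timepoint=1e9)
    expected = small_config.mix_ratio * small_mirnome["plateau"].where(
        ~small_mirnome["specific"], small_mirnome["plateau"])
    assert np.allclose(tinf.mirnas["meth_frac"], expected)


def test_profiles_mix_zero_removes_specific(small_config, small_mirnome):
    truth = simulate_profiles(small_config, small_mirnome, mix_ratio=0.0)
    spec = truth.mirnas["specific"]
    assert (truth.mirnas.loc[spec, "molecules"] == 0.0).all()
    assert (truth.mirnas.loc[~spec, "molecules"] > 0.0).all()


def test_library_deterministic_for_fixed_seed(small_config, small_mirnome, panel):
    truth = simulate_profiles(small_config, small_mirnome)
    recs = []
    for _ in range(2):
        rng = np.random.default_rng(99)
        r, _ = simulate_library(truth, True, panel, small_config, rng)
        recs.append(r)
    assert recs[0] == recs[1]


def test_complete_depletion_when_leak_zero(small_config, small_mirnome, panel):
    from dataclasses import replace
    cfg = replace(small_config, oxidation_leak=0.0, depth=20000)
    truth = simulate_profiles(cfg, small_mirnome, timepoint=0.0)  # all m=0
    rng = np.random.default_rng(5)
    _, tr = simulate_library(truth, True, panel, cfg, rng)
    mir_reads = tr[tr["kind"] == "mirna"]
    assert len(mir_reads) == 0
    # methylated spike-ins still present, unmethylated fully depleted
    by = tr.groupby("origin").size()
    amounts = dict(zip(panel.ids, panel.amounts))
    abundant_meth = [i for i, m in zip(panel.ids, panel.methylated)
                     if m and amounts[i] >= 5]
    unmeth_ids = [i for i, m in zip(panel.ids, panel.methylated) if not m]
    assert all(by.get(i, 0) > 0 for i in abundant_meth)
    assert all(by.get(i, 0) == 0 for i in unmeth_ids)


def test_read_counts_multinomial_goodness_of_fit(small_mirnome, panel):
    cfg = SimConfig(seed=7, n_mirnas=8, depth=100_000, seq_error=0.0)
    truth = simulate_profiles(cfg, small_mirnome)
    rng = np.random.default_rng(17)
    _, tr = simulate_library(truth, False, panel, cfg, rng)
    obs = tr.groupby("origin").size()
    mol = truth.mirnas["molecules"]
    probs = pd.concat([
        mol / mol.sum() * (1 - cfg.spike_frac),
        truth.spikeins["amol_per_ug"] / truth.spikeins["amol_per_ug"].sum()
        * cfg.spike_frac,
    ])
    exp = probs * cfg.depth
    keep = exp.index[exp >= 5]  # chi-square validity
    o = obs.reindex(keep).fillna(0.0)
    e = exp.loc[keep] * o.sum() / exp.loc[keep].sum()
    _, pval = sps.chisquare(o, e)
    assert pval > 0.001


def test_oxidation_acts_as_independent_thinning(panel):
    # E[ox]/E[unox] = m + leak·(1−m) per species, with the species' own leak
    cfg = SimConfig(seed=8, n_mirnas=6, depth=200_000, seq_error=0.0,
                    n_specific=0)
    ref = make_reference(cfg)
    mirnome = draw_mirnome(cfg, ref)
    truth = simulate_profiles(cfg, mirnome, timepoint=24.0)
    rng = np.random.default_rng(3)
    _, un = simulate_library(truth, False, panel, cfg, rng)
    _, ox = simulate_library(truth, True, panel, cfg, rng)
    cu = un.groupby("origin").size()
    co = ox.groupby("origin").size()
    for name in list(truth.mirnas.index) + list(truth.spikeins.index):
        n_u = cu.get(name, 0)
        if n_u < 500:
            continue
        expected = expected_ox_unox(truth, name)
        se = np.sqrt(expected * (1 - expected) / n_u + expected / n_u)
        assert abs(co.get(name, 0) / n_u - expected) < 4 * se + 1e-9


def test_fully_methylated_spikein_unaffected_by_oxidation(panel):
    cfg = SimConfig(seed=9, n_mirnas=4, depth=150_000, seq_error=0.0)
    ref = make_reference(cfg)
    truth = simulate_profiles(cfg, draw_mirnome(cfg, ref))
    rng = np.random.default_rng(4)
    _, un = simulate_library(truth, False, panel, cfg, rng)
    _, ox = simulate_library(truth, True, panel, cfg, rng)
    for sid, meth in zip(panel.ids, panel.methylated):
        if not meth:
            continue
        n_u = (un["origin"] == sid).sum()
        n_o = (ox["origin"] == sid).sum()
        assert abs(n_o - n_u) < 4 * np.sqrt(n_u + n_o + 1)


def test_error_free_roundtrip_recovers_umis_and_inserts(small_config,
                                                        small_mirnome, panel):
    truth = simulate_profiles(small_config, small_mirnome)
    rng = np.random.default_rng(21)
    records, tr = simulate_library(truth, False, panel, small_config, rng)
    stats, parsed = parse_records(records, small_config.srbc)
    assert stats.counts["ok"] == stats.total == len(tr)
    truth_by_read = tr.set_index("read")
    for name, pr in parsed:
        row = truth_by_read.loc[name]
        assert pr.insert == row["insert"]
        assert pr.umi == row["umi"]
        assert pr.srbc == row["srbc"]


def test_planted_contaminants_counted_as_wrong_srbc(small_config,
                                                    small_mirnome, panel):
    from dataclasses import replace
    truth = simulate_profiles(small_config, small_mirnome)
    rng = np.random.default_rng(31)
    own, _ = simulate_library(truth, False, panel, small_config, rng)
    other_cfg = replace(small_config, srbc="TAGCA")
    contam, _ = simulate_library(truth, False, panel, other_cfg,
                                 np.random.default_rng(32))
    contam = [(f"c_{n}", s, q) for n, s, q in contam[:500]]
    stats, _ = parse_records(list(own) + contam, small_config.srbc)
    assert stats.counts["wrong_srbc"] == 500


def test_unoxidized_profile_independent_of_methyltransferase(small_mirnome,
                                                             panel):
    # expressing the methyltransferase must not change unoxidized abundances
    from mimeseq import sample_concordance
    cfg = SimConfig(seed=7, n_mirnas=8, depth=50_000, seq_error=0.0)
    with_enzyme = simulate_profiles(cfg, small_mirnome, methylated=True)
    without = simulate_profiles(cfg, small_mirnome, methylated=False)
    a = simulate_library(with_enzyme, False, panel, cfg,
                         np.random.default_rng(41))[1]
    b = simulate_library(without, False, panel, cfg,
                         np.random.default_rng(42))[1]
    ca = a[a.kind == "mirna"].groupby("origin").size()
    cb = b[b.kind == "mirna"].groupby("origin").size()
    shared = ca.index.intersection(cb.index)
    assert sample_concordance(ca[shared].astype(float),
                              cb[shared].astype(float)) > 0.95


def test_degraded_quality_mode_exercises_quality_filter(small_config,
                                                        small_mirnome, panel):
    from dataclasses import replace
    cfg = replace(small_config, quality_mode="degraded", degraded_frac=0.2)
    truth = simulate_profiles(cfg, small_mirnome)
    rng = np.random.default_rng(6)
    records, _ = simulate_library(truth, False, panel, cfg, rng)
    stats, _ = parse_records(records, cfg.srbc)
    frac = stats.counts["low_quality"] / stats.total
    assert 0.1 < frac < 0.3


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(depth=0)
    with pytest.raises(ValueError):
        SimConfig(srbc="ACGTAC")
    with pytest.raises(ValueError):
        SimConfig(oxidation_leak=1.5)
    with pytest.raises(ValueError):
        SimConfig(n_mirnas=2, n_specific=3)
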