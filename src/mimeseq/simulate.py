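"""Synthetic mime-seq assay generator.

Emulates the full assay on desk scale so every pipeline stage is testable
without external data: a miRNA transcriptome with annotated hairpins and
matures (optionally including duplicated families), two cell populations
(methyltransferase-expressing and wild-type) mixed at a chosen ratio,
single-exponential methylation kinetics m_i(t) = M_i·(1 − exp(−k_i·t)),
spike-ins of known amounts, periodate oxidation as independent per-molecule
thinning, isomiR end heterogeneity, non-templated 3' tails, UMIs, sample
barcodes and sequencing errors.

Reads follow the shared layout [4 random nt][insert][UMI 6][sRBC 5][adapter],
padded with random bases to the read length. Every generated read is recorded
in a ground-truth table.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io
from .layout import DEFAULT_ADAPTER, DNA, HEAD_PAD, SRBC_LEN, UMI_LEN
from .mapping import Annotation, revcomp
from .spikeins import SpikeInPanel

# Synthetic spike-in panel: sequences are fixed arbitrary 22-mers (stand-ins for
# a published panel, generated once); amounts span ~3.4 orders of magnitude.
_PANEL_ROWS = [
    ("mX1", "TACGCTAGGTCAACTGGATCAG", True, 500.0),
    ("mX2", "GGATCCTAAGCGTACGTTCAAC", True, 50.0),
    ("mX3", "CAGTTAGCCGATAACGTGGTCA", True, 5.0),
    ("mX4", "TTGACGGCATCTAGCAGATCCA", True, 0.5),
    ("X1", "ACCGTTAGACGGTTCAATGCTG", False, 200.0),
    ("X2", "GTCAATGGCTTACAGCGATACG", False, 20.0),
    ("X3", "CGGATAACTGCATGGTTCGAGT", False, 2.0),
    ("X4", "TGCATCGAGTTAGGCACTGATC", False, 0.2),
]


def default_panel() -> SpikeInPanel:
    """The default synthetic spike-in panel (4 methylated + 4 unmethylated)."""
    return SpikeInPanel(
        ids=[r[0] for r in _PANEL_ROWS],
        sequences=[r[1] for r in _PANEL_ROWS],
        methylated=[r[2] for r in _PANEL_ROWS],
        amounts=[r[3] for r in _PANEL_ROWS],
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic assay."""

    seed: int = 0
    n_mirnas: int = 60
    n_specific: int = 1
    n_families: int = 0          # duplicated-mature pairs (multimappers)
    star_prob: float = 0.5       # chance a hairpin carries a second (star) mature
    abundance_logmean: float = 0.0
    abundance_logsd: float = 1.5
    specific_log_shift: float = 3.0   # specific miRNAs emulate abundant markers
    specific_logsd: float = 0.3
    mix_ratio: float = 1.0       # fraction of methyltransferase-expressing cells
    plateau_range: tuple[float, float] = (0.55, 0.95)  # per-miRNA M_i
    rate_range: tuple[float, float] = (0.04, 0.20)     # per-miRNA k_i, per hour
    timepoints: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 48.0)
    oxidation_leak: float = 0.02       # unmethylated spike-in survival under NaIO4
    mirna_leak_factor: float = 0.1     # endogenous unmethylated miRNAs survive
                                       # at oxidation_leak * this factor
    depth: int = 300_000
    seq_error: float = 0.001
    isomir_sd: float = 0.8
    isomir_max: int = 2          # offsets clipped so every insert stays >= 18 nt
    tail_prob: float = 0.15
    spike_frac: float = 0.025    # expected spike-in share of the library
    srbc: str = "CGATC"
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 65
    mature_len: int = 22
    quality_mode: str = "constant"  # or "degraded"
    degraded_frac: float = 0.05

    def __post_init__(self):
        probs = (self.mix_ratio, self.oxidation_leak, self.seq_error,
                 self.tail_prob, self.spike_frac, self.star_prob,
                 self.mirna_leak_factor, *self.plateau_range)
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if len(self.srbc) != SRBC_LEN or set(self.srbc) - set(DNA):
            raise ValueError(f"srbc must be {SRBC_LEN} nt over ACGT")
        if set(self.adapter) - set(DNA):
            raise ValueError("adapter must be over ACGT")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be non-negative")
        if self.n_mirnas < 1 or self.n_specific > self.n_mirnas:
            raise ValueError("need 1 <= n_specific <= n_mirnas")


@dataclass
class Reference:
    """Synthetic transcriptome: contigs plus contig-coordinate annotations."""

    contigs: dict[str, str]
    annotations: list[Annotation]

    def write(self, fasta: str | Path, gff3: str | Path) -> None:
        io.write_fasta(self.contigs, fasta)
        io.write_gff3(self.annotations, gff3)

    def mature_oriented(self, name: str) -> str:
        """Mature sequence in miRNA (5'->3') orientation."""
        a = next(x for x in self.annotations if x.kind == "mature" and x.name == name)
        s = self.contigs[a.contig][a.start:a.end]
        return s if a.strand == "+" else revcomp(s)


@dataclass
class TruthTable:
    """Ground truth for one simulated sample condition.

    ``mirnas`` carries, per miRNA: molecule count in the mix, methylated
    fraction at the sampled timepoint, origin population, specific flag and the
    extended sequence template used to synthesize isomiR inserts. ``spikeins``
    carries the panel amounts.
    """

    mirnas: pd.DataFrame
    spikeins: pd.DataFrame
    config: SimConfig


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, n))


def make_reference(config: SimConfig) -> Reference:
    """Random contigs, each embedding one hairpin with 1–2 mature annotations.

    With ``n_families > 0``, the first ``n_families`` mature 22-mers are
    duplicated onto an extra contig each (same strand orientation), creating
    genuine multimappers (NH = 2).
    """
    rng = np.random.default_rng([config.seed, 11])
    margin = config.isomir_max + 6
    contigs: dict[str, str] = {}
    annotations: list[Annotation] = []
    seen_kmers: set[str] = set()

    def fresh_contig(length: int) -> str:
        # reject contigs sharing an 18-mer (either strand) with earlier ones,
        # so exact-prefix hits are unambiguous by construction
        while True:
            s = _rand_seq(rng, length)
            kmers = {s[i:i + 18] for i in range(len(s) - 17)}
            kmers |= {revcomp(k) for k in kmers}
            if not (kmers & seen_kmers):
                seen_kmers.update(kmers)
                return s

    for i in range(config.n_mirnas):
        name = f"mir-{i + 1}"
        clen = 110
        seq = fresh_contig(clen)
        strand = "+" if rng.random() < 0.5 else "-"
        pre_lo, pre_hi = 10, clen - 10
        m_lo = pre_lo + margin
        m_hi = m_lo + config.mature_len
        cid = f"ctg{i + 1}"
        contigs[cid] = seq
        annotations.append(Annotation(cid, "pre_mirna", f"{name}-pre",
                                      pre_lo, pre_hi, strand))
        annotations.append(Annotation(cid, "mature", name, m_lo, m_hi, strand))
        if rng.random() < config.star_prob:
            s_lo = m_hi + 8
            annotations.append(Annotation(cid, "mature", f"{name}-star",
                                          s_lo, s_lo + config.mature_len, strand))

    for f in range(config.n_families):
        donor = f"mir-{f + 1}"
        a = next(x for x in annotations if x.kind == "mature" and x.name == donor)
        dcid = a.contig
        clen = 110
        host = list(fresh_contig(clen))
        m_lo = 10 + margin
        pad = config.isomir_max + 1  # include flanking bases on both sides so
        # the duplicate locus has the same templated context as the donor
        dup = contigs[dcid][a.start - pad: a.end + pad]
        host[m_lo - pad: m_lo - pad + len(dup)] = dup
        cid = f"ctg{config.n_mirnas + f + 1}"
        contigs[cid] = "".join(host)
        annotations.append(Annotation(cid, "pre_mirna", f"{donor}-P2-pre",
                                      10, clen - 10, a.strand))
        annotations.append(Annotation(cid, "mature", f"{donor}-P2",
                                      m_lo, m_lo + config.mature_len, a.strand))
    return Reference(contigs, annotations)


def draw_mirnome(config: SimConfig, reference: Reference) -> pd.DataFrame:
    """Per-miRNA latent parameters, fixed across the libraries of an experiment.

    Shared miRNAs have equal per-cell abundance in both populations; specific
    miRNAs exist only in the methyltransferase-expressing population and are
    drawn at marker-like high abundance.
    """
    rng = np.random.default_rng([config.seed, 23])
    names = [f"mir-{i + 1}" for i in range(config.n_mirnas)]
    abund = np.exp(rng.normal(config.abundance_logmean, config.abundance_logsd,
                              config.n_mirnas))
    specific = np.zeros(config.n_mirnas, dtype=bool)
    if config.n_specific:
        idx = rng.choice(config.n_mirnas, size=config.n_specific, replace=False)
        specific[idx] = True
        abund[idx] = np.exp(rng.normal(
            config.abundance_logmean + config.specific_log_shift,
            config.specific_logsd, config.n_specific))
    lo, hi = config.plateau_range
    plateau = rng.uniform(lo, hi, config.n_mirnas)
    rate = rng.uniform(*config.rate_range, config.n_mirnas)
    df = pd.DataFrame({
        "name": names, "abundance": abund, "specific": specific,
        "plateau": plateau, "rate": rate,
    }).set_index("name")
    df["template"], df["next_base"] = zip(*(
        _extended_template(reference, n, config.isomir_max) for n in df.index))
    return df


def _extended_template(reference: Reference, name: str, pad: int) -> tuple[str, str]:
    """Mature sequence ± pad genomic context, miRNA-oriented, plus the first
    templated base beyond the padded 3' end (used to keep tails non-templated)."""
    a = next(x for x in reference.annotations
             if x.kind == "mature" and x.name == name)
    seq = reference.contigs[a.contig]
    if a.strand == "+":
        ext = seq[a.start - pad: a.end + pad]
        nxt = seq[a.end + pad]
    else:
        ext = revcomp(seq[a.start - pad: a.end + pad])
        nxt = revcomp(seq[a.start - pad - 1])
    return ext, nxt


def simulate_profiles(config: SimConfig, mirnome: pd.DataFrame,
                      mix_ratio: float | None = None,
                      timepoint: float | None = None,
                      panel: SpikeInPanel | None = None,
                      methylated: bool = True) -> TruthTable:
    """Ground-truth molecule counts and methylated fractions for one condition.

    Methylation follows m_i(t) = M_i·(1 − exp(−k_i·t)). In a mix with a
    fraction ``mix_ratio`` of methyltransferase-expressing cells, shared miRNAs
    are methylated at mix_ratio·m_i(t) (only molecules from enzyme-positive
    cells are methylated) while specific miRNAs, present only in those cells,
    are methylated at m_i(t) and contribute mix_ratio-scaled molecule counts.
    ``methylated=False`` emulates a genotype control without the enzyme.
    """
    rho = config.mix_ratio if mix_ratio is None else mix_ratio
    t = max(config.timepoints) if timepoint is None else timepoint
    panel = panel or default_panel()
    m_t = mirnome["plateau"] * -np.expm1(-mirnome["rate"] * t)
    spec = mirnome["specific"]
    molecules = mirnome["abundance"].where(~spec, mirnome["abundance"] * rho)
    meth = (rho * m_t).where(~spec, m_t)
    if not methylated:
        meth = meth * 0.0
    df = pd.DataFrame({
        "molecules": molecules, "meth_frac": meth,
        "origin": np.where(spec, "specific", "shared"),
        "specific": spec,
        "template": mirnome["template"], "next_base": mirnome["next_base"],
    })
    sp = panel.frame.set_index("id")
    return TruthTable(df, sp, replace(config, mix_ratio=rho))


def simulate_library(truth: TruthTable, oxidized: bool, panel: SpikeInPanel,
                     config: SimConfig, rng: np.random.Generator,
                     fastq_path: str | Path | None = None,
                     truth_path: str | Path | None = None):
    """Emit one sequencing library plus its per-read ground truth.

    Oxidation is independent thinning: methylated molecules always survive;
    unmethylated spike-ins survive with probability ``oxidation_leak`` and
    unmethylated endogenous miRNAs with ``oxidation_leak·mirna_leak_factor``
    (the unmethylated spike-ins mark the maximum expected survival of an
    unmethylated species). Tails are drawn so their first base differs from
    the next templated base, keeping them genuinely non-templated.

    Returns (records, read_truth): records are (name, seq, qual) tuples.
    """
    cfg = config
    mir = truth.mirnas
    mol = mir["molecules"].to_numpy(float)
    amounts = truth.spikeins["amol_per_ug"].to_numpy(float)
    spike_meth = truth.spikeins["methylated"].astype(bool).to_numpy()
    mir_w = (mol / mol.sum() * (1 - cfg.spike_frac)) if mol.sum() > 0 else np.zeros(len(mol))
    spike_w = amounts / amounts.sum() * cfg.spike_frac
    if mol.sum() == 0:
        spike_w = spike_w / spike_w.sum()
    p = np.concatenate([mir_w, spike_w])

    names = list(mir.index) + list(truth.spikeins.index)
    kinds = ["mirna"] * len(mir) + ["spikein"] * len(truth.spikeins)
    meth_frac = np.concatenate([
        mir["meth_frac"].to_numpy(float),
        spike_meth.astype(float),
    ])
    leak = np.concatenate([
        np.full(len(mir), cfg.oxidation_leak * cfg.mirna_leak_factor),
        np.where(spike_meth, 1.0, cfg.oxidation_leak),
    ])

    drawn = rng.multinomial(cfg.depth, p)
    n_meth = rng.binomial(drawn, meth_frac)
    if oxidized:
        n_unmeth = rng.binomial(drawn - n_meth, leak)
    else:
        n_unmeth = drawn - n_meth
    totals = (n_meth + n_unmeth).astype(int)
    n = int(totals.sum())
    n_mirna_origins = len(mir)

    # per-read arrays, origin-major order (shuffled at the end)
    origin_idx = np.repeat(np.arange(len(names)), totals)
    is_mir = origin_idx < n_mirna_origins
    methylated = np.zeros(n, dtype=bool)
    offs = np.cumsum(np.concatenate([[0], totals]))
    for oi in range(len(names)):
        methylated[offs[oi]: offs[oi] + int(n_meth[oi])] = True

    mx, mlen = cfg.isomir_max, cfg.mature_len
    off5 = np.zeros(n, dtype=int)
    off3 = np.zeros(n, dtype=int)
    nm = int(is_mir.sum())
    off5[is_mir] = np.clip(np.rint(rng.normal(0, cfg.isomir_sd, nm)), -mx, mx)
    off3[is_mir] = np.clip(np.rint(rng.normal(0, cfg.isomir_sd, nm)), -mx, mx)

    # tails: first base drawn to differ from the next templated base
    tailed = is_mir & (rng.random(n) < cfg.tail_prob)
    tlen = np.zeros(n, dtype=int)
    tlen[tailed] = rng.choice([1, 2, 3], int(tailed.sum()), p=[0.6, 0.3, 0.1])
    code = {c: k for k, c in enumerate(DNA)}
    templates = mir["template"].tolist()
    # blocked[oi][off3+mx] = templated base right after an insert ending at off3
    blocked_codes = np.zeros((n_mirna_origins, 2 * mx + 1), dtype=np.uint8)
    for oi in range(n_mirna_origins):
        tpl, nxt = templates[oi], mir["next_base"].iloc[oi]
        for d in range(-mx, mx + 1):
            b = mx + mlen + d
            blocked_codes[oi, d + mx] = code[tpl[b] if b < len(tpl) else nxt]
    base = np.frombuffer(b"ACGT", dtype=np.uint8)
    blocked = np.zeros(n, dtype=np.uint8)
    blocked[is_mir] = blocked_codes[origin_idx[is_mir], off3[is_mir] + mx]
    first_tail = base[(blocked + rng.integers(1, 4, n)) % 4]
    extra_blob = base[rng.integers(0, 4, n * 2)].tobytes().decode("ascii")

    spike_seqs = truth.spikeins["sequence"].tolist()
    inserts: list[str] = [""] * n
    tails: list[str] = [""] * n
    ft = first_tail.tobytes().decode("ascii")
    for i in range(n):
        oi = origin_idx[i]
        if is_mir[i]:
            s = templates[oi][mx + off5[i]: mx + mlen + off3[i]]
            if tlen[i]:
                t = ft[i] + extra_blob[2 * i: 2 * i + tlen[i] - 1]
                tails[i] = t
                s = s + t
            inserts[i] = s
        else:
            inserts[i] = spike_seqs[oi - n_mirna_origins]

    order = rng.permutation(n)
    L = cfg.read_length
    umi_blob = base[rng.integers(0, 4, n * UMI_LEN)].tobytes().decode("ascii")
    head_blob = base[rng.integers(0, 4, n * HEAD_PAD)].tobytes().decode("ascii")
    pad_blob = base[rng.integers(0, 4, n * 12 + L)].tobytes().decode("ascii")
    tag = cfg.srbc + cfg.adapter
    umi_strs: list[str] = [""] * n
    reads: list[str] = [""] * n
    pad_off = 0
    for row_i in range(n):
        src = order[row_i]
        umi = umi_blob[row_i * UMI_LEN: (row_i + 1) * UMI_LEN]
        head = head_blob[row_i * HEAD_PAD: (row_i + 1) * HEAD_PAD]
        s = head + inserts[src] + umi + tag
        short = L - len(s)
        if short > 0:
            s += pad_blob[pad_off: pad_off + short]
            pad_off += short
        elif short < 0:
            s = s[:L]
        umi_strs[row_i] = umi
        reads[row_i] = s

    blob = "".join(reads)
    if cfg.seq_error > 0 and n > 0:
        arr = np.frombuffer(blob.encode("ascii"), dtype=np.uint8).copy()
        n_err = rng.binomial(n * L, cfg.seq_error)
        flat = rng.integers(0, n * L, n_err)
        lut = np.zeros(256, dtype=np.uint8)
        for k, c in enumerate(b"ACGT"):
            lut[c] = k
        arr[flat] = base[(lut[arr[flat]] + rng.integers(1, 4, n_err)) % 4]
        blob = arr.tobytes().decode("ascii")

    qual = "I" * L
    quals = [qual] * n
    if cfg.quality_mode == "degraded" and n:
        bad = rng.random(n) < cfg.degraded_frac
        badq = "#" * L
        quals = [badq if b else qual for b in bad]
    records = [(f"r{i:07d}", blob[i * L:(i + 1) * L], quals[i]) for i in range(n)]

    name_arr = np.array(names, dtype=object)
    tr = pd.DataFrame({
        "read": [r[0] for r in records],
        "origin": name_arr[origin_idx[order]],
        "kind": np.where(is_mir[order], "mirna", "spikein"),
        "methylated": methylated[order],
        "off5": off5[order],
        "off3": off3[order],
        "tail": [tails[s] for s in order],
        "insert": [inserts[s] for s in order],
        "umi": umi_strs,
    })
    tr["srbc"] = cfg.srbc

    if fastq_path is not None:
        io.write_fastq(records, fastq_path)
    if truth_path is not None:
        tr.to_csv(truth_path, sep="\t", index=False)
    return records, tr


# distinct sample barcodes for multi-library experiments
_SRBCS = ("CGATC", "TAGCA", "GCTTG", "ATCGT", "TCAAG", "GATAC", "CTGGA",
          "AGCCT", "TTGCG", "CAGTT", "GTACA", "ACTGC", "TCGGA", "AATCG",
          "GGCAT", "CTATG")


def simulate_experiment(config: SimConfig, outdir: str | Path,
                        kind: str = "mixing",
                        ratios: Sequence[float] = (1.0, 0.01, 0.001),
                        control: bool = False,
                        write_truth: bool = True) -> dict:
    """Write a complete synthetic experiment ready for ``run_experiment``.

    ``kind="mixing"`` emits one ox/unox library pair per mixing ratio at the
    final timepoint (ratio 1.0 is the pure reference population);
    ``kind="timecourse"`` emits one pair per configured timepoint at the
    configured mix ratio. ``control=True`` silences the methyltransferase
    (every miRNA unmethylated), emulating a genotype control.

    Returns a manifest with the run-config path, the latent miRNome and the
    per-condition truth tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = make_reference(config)
    ref.write(outdir / "reference.fa", outdir / "reference.gff3")
    panel = default_panel()
    panel.to_tsv(outdir / "panel.tsv")
    mirnome = draw_mirnome(config, ref)
    mirnome.drop(columns=["template", "next_base"]).to_csv(
        outdir / "mirnome.tsv", sep="\t")

    if kind == "mixing":
        conds = [(f"mix_{r:g}", r, max(config.timepoints), None) for r in ratios]
    elif kind == "timecourse":
        conds = [(f"t{t:g}", config.mix_ratio, t, t) for t in config.timepoints]
    else:
        raise ValueError(f"unknown experiment kind {kind!r}")

    rows = []
    truths: dict[str, TruthTable] = {}
    lib_i = 0
    for group, rho, t, tp in conds:
        truth = simulate_profiles(config, mirnome, mix_ratio=rho, timepoint=t,
                                  panel=panel, methylated=not control)
        truths[group] = truth
        for treatment, oxidized in (("unoxidized", False), ("oxidized", True)):
            srbc = _SRBCS[lib_i % len(_SRBCS)]
            lib_id = f"{group}_{treatment}"
            rng = np.random.default_rng([config.seed, 1000 + lib_i])
            simulate_library(
                truth, oxidized, panel, replace(config, srbc=srbc), rng,
                fastq_path=outdir / f"{lib_id}.fastq",
                truth_path=(outdir / f"{lib_id}.truth.tsv") if write_truth else None)
            rows.append({"library_id": lib_id, "fastq": f"{lib_id}.fastq",
                         "srbc": srbc, "treatment": treatment, "group": group,
                         "timepoint": tp})
            lib_i += 1

    pd.DataFrame(rows).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    run_cfg = {
        "reference": {"fasta": "reference.fa", "gff3": "reference.gff3"},
        "panel": "panel.tsv",
        "outdir": "results",
        "samples": rows,
        "thresholds": {"expression_floor": 0.5, "cumulative": 0.98,
                       "rate_window": [6.0, 12.0]},
    }
    if kind == "mixing" and any(r == 1.0 for r in ratios):
        run_cfg["analysis"] = {"reference_group": "mix_1"}
    run_yaml = outdir / "run.yaml"
    with open(run_yaml, "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=False)
    return {"outdir": str(outdir), "run_yaml": str(run_yaml),
            "reference": ref, "panel": panel, "mirnome": mirnome,
            "truths": truths, "groups": [c[0] for c in conds]}


def expected_ox_unox(truth: TruthTable, name: str) -> float:
    """E[ox count]/E[unox count] for one species under the thinning model."""
    cfg = truth.config
    if name in truth.mirnas.index:
        m = float(truth.mirnas.loc[name, "meth_frac"])
        leak = cfg.oxidation_leak * cfg.mirna_leak_factor
    else:
        m = 1.0 if bool(truth.spikeins.loc[name, "methylated"]) else 0.0
        leak = cfg.oxidation_leak
    return m + leak * (1 - m)
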