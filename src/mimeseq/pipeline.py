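"""End-to-end orchestration: parse → spike-in filter → map → count → normalize,
then paired ox/unox analyses (timecourse methylation rates, mixing calls).

All randomness lives in the simulator; given fixed inputs every stage here is
deterministic, and read attrition is accounted for exactly at every step.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import counting, io, mapping, spikeins, stats
from .parsing import ParseParams, ParseStats, parse_fastq
from .spikeins import SizeFactor, SpikeInPanel
from .stats import CallResult, Methylome, Thresholds


@dataclass
class SampleSpec:
    library_id: str
    fastq: str
    srbc: str
    treatment: str  # "oxidized" | "unoxidized"
    group: str = "all"
    timepoint: float | None = None

    def __post_init__(self):
        if self.treatment not in ("oxidized", "unoxidized"):
            raise ValueError(f"{self.library_id}: bad treatment {self.treatment!r}")


@dataclass
class RunConfig:
    reference_fasta: str
    reference_gff3: str
    panel: str
    outdir: str
    samples: list[SampleSpec]
    parse: ParseParams = field(default_factory=ParseParams)
    min_prefix: int = 18
    tol5: int = 5
    tol3: int = 5
    thresholds: Thresholds = field(default_factory=Thresholds)
    reference_group: str | None = None  # pure population for mixing analyses
    user_cutoff: float | None = None    # fallback when the panel lacks
                                        # unmethylated members

    def __post_init__(self):
        ids = [s.library_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("library ids must be unique")
        for path in (self.reference_fasta, self.reference_gff3, self.panel):
            if not Path(path).exists():
                raise FileNotFoundError(f"missing input: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def _p(x):
            q = Path(x)
            return str(q if q.is_absolute() else base / q)

        samples = [SampleSpec(
            library_id=row["library_id"], fastq=_p(row["fastq"]),
            srbc=row["srbc"], treatment=row["treatment"],
            group=str(row.get("group", "all")),
            timepoint=row.get("timepoint"),
        ) for row in raw["samples"]]
        th = raw.get("thresholds", {})
        return cls(
            reference_fasta=_p(raw["reference"]["fasta"]),
            reference_gff3=_p(raw["reference"]["gff3"]),
            panel=_p(raw["panel"]),
            outdir=_p(raw.get("outdir", "out")),
            samples=samples,
            parse=ParseParams(**raw.get("parse", {})),
            min_prefix=raw.get("mapping", {}).get("min_prefix", 18),
            tol5=raw.get("counting", {}).get("tol5", 5),
            tol3=raw.get("counting", {}).get("tol3", 5),
            thresholds=Thresholds(
                expression_floor=th.get("expression_floor", 0.5),
                cumulative=th.get("cumulative", 0.98),
                rate_window=tuple(th.get("rate_window", (6.0, 12.0))),
            ),
            reference_group=raw.get("analysis", {}).get("reference_group"),
            user_cutoff=raw.get("analysis", {}).get("user_cutoff"),
        )


@dataclass
class SampleTable:
    """Per-library result: raw weighted counts and amol/µg expression."""

    library_id: str
    treatment: str
    group: str
    timepoint: float | None
    mature_raw: pd.Series
    mature_norm: pd.Series
    premirna_raw: pd.Series
    tails: pd.Series
    spike_counts: pd.Series
    size_factor: SizeFactor
    parse_stats: ParseStats
    attrition: dict


def _spec(cfg: RunConfig, library_id: str) -> SampleSpec:
    for s in cfg.samples:
        if s.library_id == library_id:
            return s
    raise KeyError(f"unknown library {library_id}")


def quantify_survivors(survivors, pstats: ParseStats, panel: SpikeInPanel,
                       index: mapping.PrefixIndex, annotations: list,
                       min_prefix: int = 18, tol5: int = 5, tol3: int = 5,
                       library_id: str = "library", treatment: str = "unoxidized",
                       group: str = "all", timepoint: float | None = None
                       ) -> SampleTable:
    """Spike-in filter → map → count → normalize for already-parsed inserts.

    ``survivors`` are the (name, insert, qual, umi) tuples of reads that passed
    parsing. Unique insert sequences are processed once and re-weighted by
    their read multiplicity.
    """
    weights = Counter(insert for _, insert, _, _ in survivors)
    spike_counts: Counter = Counter()
    mirna_weights: dict[str, int] = {}
    for insert, w in weights.items():
        sid = spikeins.match_spikein(insert, panel)
        if sid is not None:
            spike_counts[sid] += w
        else:
            mirna_weights[insert] = w

    aln_map = mapping.map_inserts(mirna_weights, index, min_prefix)
    alignments = [a for alns in aln_map.values() for a in alns]
    n_spike = sum(spike_counts.values())
    n_mapped = sum(mirna_weights[i] for i, alns in aln_map.items() if alns)
    n_ok = pstats.counts["ok"]

    mature = counting.count_mature(alignments, annotations, tol5, tol3,
                                   weights=mirna_weights)
    pre = counting.count_premirna(alignments, annotations, weights=mirna_weights)
    tails = counting.tabulate_tails(alignments, annotations, tol5, tol3,
                                    weights=mirna_weights)
    sf = spikeins.size_factor(spike_counts, panel)
    norm = spikeins.normalize(mature, sf).rename("amol_per_ug")

    attrition = {
        "total_reads": pstats.total,
        **{f"filtered_{k}": v for k, v in pstats.counts.items() if k != "ok"},
        "ok": n_ok,
        "spikein": n_spike,
        "mapped": n_mapped,
        "unmapped": n_ok - n_spike - n_mapped,
    }
    return SampleTable(library_id, treatment, group, timepoint,
                       mature, norm, pre, tails,
                       pd.Series(dict(spike_counts), dtype=float).sort_index(),
                       sf, pstats, attrition)


def run_sample(cfg: RunConfig, library_id: str,
               index: mapping.PrefixIndex | None = None,
               annotations: list | None = None,
               panel: SpikeInPanel | None = None,
               write: bool = True) -> SampleTable:
    """Process one library through parse → spike-in filter → map → count → normalize."""
    spec = _spec(cfg, library_id)
    panel = panel or SpikeInPanel.from_tsv(cfg.panel)
    if index is None:
        index = mapping.build_index(io.read_fasta(cfg.reference_fasta),
                                    seed_len=cfg.min_prefix)
    if annotations is None:
        annotations = io.read_gff3(cfg.reference_gff3)

    outdir = Path(cfg.outdir) / library_id
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    pstats, survivors = parse_fastq(
        spec.fastq, spec.srbc, cfg.parse,
        stats_path=(outdir / "parse_stats.tsv") if write else None)
    table = quantify_survivors(
        survivors, pstats, panel, index, annotations,
        cfg.min_prefix, cfg.tol5, cfg.tol3,
        library_id=library_id, treatment=spec.treatment,
        group=spec.group, timepoint=spec.timepoint)
    mature, pre, tails, norm = (table.mature_raw, table.premirna_raw,
                                table.tails, table.mature_norm)
    spike_counts = table.spike_counts
    if write:
        counting.counts_to_tsv(mature, pre, outdir / "counts.tsv")
        norm.to_frame().to_csv(outdir / "expression_amol_per_ug.tsv", sep="\t")
        tails.to_frame().to_csv(outdir / "tails.tsv", sep="\t")
        spikeins.spikein_counts_tsv(spike_counts, panel, outdir / "spikeins.tsv",
                                    total_reads=pstats.total)
    return table


@dataclass
class ExperimentResult:
    samples: dict[str, SampleTable]
    methylomes: dict[tuple[str, float | None], Methylome]
    rates: pd.Series | None
    cutoffs: dict[str, float]
    calls: dict[str, CallResult]
    reference_set: list[str] | None
    report: dict


def _pair_libraries(cfg: RunConfig) -> dict[tuple[str, float | None], dict[str, str]]:
    pairs: dict[tuple[str, float | None], dict[str, str]] = {}
    for s in cfg.samples:
        pairs.setdefault((s.group, s.timepoint), {})[s.treatment] = s.library_id
    bad = [k for k, v in pairs.items() if set(v) != {"oxidized", "unoxidized"}]
    if bad:
        raise ValueError(f"unpaired ox/unox libraries for: {sorted(bad)}")
    return pairs


def spikein_ratios(ox: SampleTable, unox: SampleTable,
                   panel: SpikeInPanel, methylated: bool) -> dict[str, float]:
    """Normalized ox/unox ratios for panel members detected in the unox library."""
    out = {}
    for sid, meth in zip(panel.ids, panel.methylated):
        if meth != methylated:
            continue
        cu = float(unox.spike_counts.get(sid, 0.0))
        if cu <= 0:
            continue
        co = float(ox.spike_counts.get(sid, 0.0))
        out[sid] = (co / ox.size_factor.value) / (cu / unox.size_factor.value)
    return out


def run_experiment(cfg: RunConfig, write: bool = True) -> ExperimentResult:
    """Run every library, then the paired ox/unox analyses.

    Produces per-(group, timepoint) methylomes, per-miRNA methylation rates when
    both rate-window timepoints exist, and — when ``reference_group`` is set —
    cell-specific calls per mix group with FP bookkeeping against the reference
    miRNome of the pure population's oxidized library.
    """
    if not cfg.samples:
        raise ValueError("empty sample sheet")
    pairs = _pair_libraries(cfg)
    panel = SpikeInPanel.from_tsv(cfg.panel)
    index = mapping.build_index(io.read_fasta(cfg.reference_fasta),
                                seed_len=cfg.min_prefix)
    annotations = io.read_gff3(cfg.reference_gff3)

    tables = {s.library_id: run_sample(cfg, s.library_id, index=index,
                                       annotations=annotations, panel=panel,
                                       write=write)
              for s in cfg.samples}

    methylomes: dict[tuple[str, float | None], Methylome] = {}
    cutoffs: dict[str, float] = {}
    for key, libs in pairs.items():
        ox, un = tables[libs["oxidized"]], tables[libs["unoxidized"]]
        methylomes[key] = stats.methylation_fraction(
            ox.mature_norm, un.mature_norm, cfg.thresholds.expression_floor)

    # methylation rates from a timecourse, when the window endpoints exist
    rates = None
    by_time = {tp: m for (_, tp), m in methylomes.items() if tp is not None}
    t1, t2 = cfg.thresholds.rate_window
    if t1 in by_time and t2 in by_time:
        pct = pd.DataFrame({tp: m.pct for tp, m in sorted(by_time.items())})
        rates = stats.methylation_rate(pct, cfg.thresholds.rate_window)

    # enrichment cutoffs and calls per group (mix libraries call against their
    # own cutoff; FP bookkeeping additionally needs a pure reference group)
    calls: dict[str, CallResult] = {}
    reference_set = None
    for key, libs in pairs.items():
        group = key[0]
        ox, un = tables[libs["oxidized"]], tables[libs["unoxidized"]]
        ratios = spikein_ratios(ox, un, panel, methylated=False)
        if len(ratios) >= 2:
            cutoffs[group] = spikeins.depletion_cutoff(list(ratios.values()))
        elif cfg.user_cutoff is not None:
            cutoffs[group] = cfg.user_cutoff
        elif cfg.reference_group is not None:
            raise ValueError(
                f"{group}: <2 unmethylated spike-in ratios and no user cutoff")
    if cfg.reference_group is not None:
        ref_keys = [k for k in pairs if k[0] == cfg.reference_group]
        if not ref_keys:
            raise ValueError(f"reference group {cfg.reference_group!r} not found")
        rk = ref_keys[0]
        ref_ox = tables[pairs[rk]["oxidized"]]
        ref_un = tables[pairs[rk]["unoxidized"]]
        expressed = stats.filter_expressed(ref_un.mature_norm,
                                           cfg.thresholds.expression_floor)
        reference_set = stats.top_cumulative_set(
            ref_ox.mature_norm.reindex(expressed).fillna(0.0),
            cfg.thresholds.cumulative)
    for key, libs in pairs.items():
        group = key[0]
        if group == cfg.reference_group or group not in cutoffs:
            continue
        ox, un = tables[libs["oxidized"]], tables[libs["unoxidized"]]
        res = stats.call_specific(ox.mature_norm, un.mature_norm,
                                  cfg.thresholds, cutoffs[group])
        if reference_set is not None:
            ev = stats.evaluate_calls(res.called, reference_set)
            res.reference = reference_set
            res.true_positives = ev["tp"]
            res.false_positives = ev["fp"]
        calls[group] = res

    report = {
        "thresholds": {
            "expression_floor": cfg.thresholds.expression_floor,
            "cumulative": cfg.thresholds.cumulative,
            "rate_window": list(cfg.thresholds.rate_window),
        },
        "attrition": {lid: t.attrition for lid, t in tables.items()},
        "size_factors": {lid: t.size_factor.value for lid, t in tables.items()},
        "cutoffs": cutoffs,
        "reference_set": reference_set,
        "calls": {g: {"called": r.called,
                      "false_positives": r.false_positives,
                      "n_fp": len(r.false_positives)}
                  for g, r in calls.items()},
        "median_pct_ox_unox": {f"{g}@{tp}": float(m.pct.median())
                               for (g, tp), m in methylomes.items()
                               if len(m.pct)},
    }
    if write:
        Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
        with open(Path(cfg.outdir) / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return ExperimentResult(tables, methylomes, rates, cutoffs, calls,
                            reference_set, report)
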