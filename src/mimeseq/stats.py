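"""Analysis layer: methylation fractions, rates, reference miRNomes, calling.

The central quantity is the percent ox/unox ratio of spike-in-normalized
expression between a periodate-oxidized and an untreated library: for a miRNA
it estimates the fraction of its molecules carrying a protective 3'-terminal
2'-O-methyl group, i.e. the fraction originating from methyltransferase-
expressing cells. Cell-type-specific miRNAs in a mixed population are called
as miRNAs that (a) pass the expression floor in the unoxidized mix, (b) rank
within the top-q cumulative share of the oxidized mix, and (c) show ox/unox
enrichment above a cutoff derived from the unmethylated spike-ins.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class Thresholds:
    """Analysis thresholds in spike-in-normalized units (amol/µg)."""

    expression_floor: float = 0.5   # mouse-style; 0.01 for human-style panels
    cumulative: float = 0.98        # reference/detection miRNome mass
    rate_window: tuple[float, float] = (6.0, 12.0)  # hours

    def __post_init__(self):
        if self.expression_floor < 0:
            raise ValueError("expression_floor must be >= 0")
        if not (0 < self.cumulative <= 1):
            raise ValueError("cumulative must be in (0, 1]")
        if self.rate_window[1] <= self.rate_window[0]:
            raise ValueError("rate window must be increasing")


@dataclass
class Methylome:
    """Per-miRNA paired ox/unox expression and percent recovery."""

    table: pd.DataFrame  # columns: unox, ox, pct_ox_unox

    @property
    def pct(self) -> pd.Series:
        return self.table["pct_ox_unox"]


@dataclass
class CallResult:
    called: list[str]
    cutoff: float
    table: pd.DataFrame  # per-called miRNA: pct_ox_unox, ox expression, rank
    reference: list[str] = field(default_factory=list)
    true_positives: list[str] = field(default_factory=list)
    false_positives: list[str] = field(default_factory=list)


def filter_expressed(unox: pd.Series, floor: float) -> pd.Index:
    """miRNAs whose unoxidized normalized expression strictly exceeds the floor."""
    unox = unox.astype(float)
    return unox.index[unox > floor]


def methylation_fraction(ox: pd.Series, unox: pd.Series, floor: float) -> Methylome:
    """Percent ox/unox for every miRNA expressed in the unoxidized library.

    Ratios are not capped: values above 100% arise from sampling noise and are
    kept as observed.
    """
    keep = filter_expressed(unox, floor)
    ox = ox.reindex(keep).fillna(0.0).astype(float)
    un = unox.loc[keep].astype(float)
    tab = pd.DataFrame({"unox": un, "ox": ox, "pct_ox_unox": 100.0 * ox / un})
    return Methylome(tab.sort_index())


def methylation_rate(pct_by_time: pd.DataFrame,
                     window: tuple[float, float] = (6.0, 12.0)) -> pd.Series:
    """Per-miRNA methylation rate in %/h: the pct slope across the window.

    ``pct_by_time`` has timepoints (hours) as columns and miRNAs as rows;
    miRNAs missing either endpoint get NaN.
    """
    t1, t2 = window
    cols = {float(c): c for c in pct_by_time.columns}
    if t1 not in cols or t2 not in cols:
        raise ValueError(f"window endpoints {window} not among timepoints")
    return ((pct_by_time[cols[t2]] - pct_by_time[cols[t1]]) / (t2 - t1)).rename("rate")


def top_cumulative_set(expr: pd.Series, q: float = 0.98) -> list[str]:
    """Smallest descending-rank prefix reaching a cumulative share q.

    Ties are broken by name for determinism; zero-expression miRNAs are never
    included (q=1 returns every nonzero miRNA).
    """
    expr = expr.astype(float)
    total = expr.sum()
    if total <= 0:
        raise ValueError("expression table is all zero")
    df = expr.rename("x").reset_index()
    df = df.sort_values(["x", df.columns[0]], ascending=[False, True])
    df = df[df["x"] > 0]
    cum = df["x"].cumsum() / total
    k = int(np.searchsorted(cum.values, q * (1 - 1e-12)) + 1)
    k = min(k, len(df))
    return df.iloc[:k, 0].tolist()


def call_specific(mix_ox: pd.Series, mix_unox: pd.Series,
                  thresholds: Thresholds, cutoff: float) -> CallResult:
    """Call miRNAs confidently present in methyltransferase-expressing cells.

    The detection set is the top-cumulative prefix of the mix's own oxidized
    library (restricted to miRNAs expressed in the unoxidized mix); calls
    additionally require ox/unox above the depletion cutoff.
    """
    expressed = filter_expressed(mix_unox, thresholds.expression_floor)
    ox = mix_ox.reindex(expressed).fillna(0.0).astype(float)
    if len(expressed) == 0 or ox.sum() <= 0:
        return CallResult([], cutoff, pd.DataFrame(
            columns=["pct_ox_unox", "ox", "rank"]))
    top = top_cumulative_set(ox, thresholds.cumulative)
    ratio = ox / mix_unox.loc[expressed].astype(float)
    rank = ox.rank(ascending=False, method="first")
    called = [m for m in top if ratio[m] > cutoff]
    tab = pd.DataFrame({
        "pct_ox_unox": 100.0 * ratio[called],
        "ox": ox[called],
        "rank": rank[called].astype(int),
    }).sort_values("rank")
    return CallResult(called, cutoff, tab)


def evaluate_calls(called: Sequence[str], reference: Sequence[str],
                   ks: Iterable[int] = (5, 10, 25, 50)) -> dict:
    """TP/FP bookkeeping against the reference miRNome of the pure population."""
    called = list(called)
    ref = list(reference)
    refset = set(ref)
    tp = [m for m in called if m in refset]
    fp = [m for m in called if m not in refset]
    topk = {k: len(set(called) & set(ref[:k])) for k in ks}
    return {"tp": tp, "fp": fp, "n_tp": len(tp), "n_fp": len(fp),
            "top_k_recovered": topk, "n_reference": len(ref)}


def sample_concordance(a: pd.Series, b: pd.Series) -> float:
    """Spearman correlation of normalized expression over the shared miRNA set."""
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least three shared miRNAs")
    rho, _ = sps.spearmanr(a.loc[shared], b.loc[shared])
    return float(rho)
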