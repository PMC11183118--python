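"""Plotting helpers mirroring the assay's standard displays.

All functions return a matplotlib Figure and never call ``show()``.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_timecourse(pct_by_time: pd.DataFrame):
    """Percent ox/unox per miRNA over induction time (median highlighted)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    t = [float(c) for c in pct_by_time.columns]
    for _, row in pct_by_time.iterrows():
        ax.plot(t, row.values, color="grey", alpha=0.15, lw=0.5)
    ax.plot(t, pct_by_time.median(axis=0).values, color="crimson", lw=2,
            label="median")
    ax.set_xlabel("induction time (h)")
    ax.set_ylabel("% ox/unox")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_mixing(ox: pd.Series, pct: pd.Series, cutoff: float,
                abundance_floor: float | None = None,
                called: list[str] | None = None):
    """Enrichment (% ox/unox) against oxidized abundance with the call gates."""
    fig, ax = plt.subplots(figsize=(5, 4))
    shared = ox.index.intersection(pct.index)
    x = ox.loc[shared].clip(lower=1e-6)
    y = pct.loc[shared].clip(lower=1e-3)
    ax.scatter(x, y, s=10, color="grey", alpha=0.6)
    if called:
        hit = [m for m in called if m in shared]
        ax.scatter(x.loc[hit], y.loc[hit], s=18, color="darkorange",
                   label="called")
    ax.axhline(100 * cutoff, ls="--", color="black", lw=1)
    if abundance_floor is not None:
        ax.axvline(abundance_floor, ls="--", color="black", lw=1)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("oxidized expression (amol/µg)")
    ax.set_ylabel("% ox/unox")
    if called:
        ax.legend()
    fig.tight_layout()
    return fig


def plot_concordance(a: pd.Series, b: pd.Series, label_a: str = "sample A",
                     label_b: str = "sample B"):
    """Log-log expression scatter between two libraries."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    shared = a.index.intersection(b.index)
    ax.scatter(a.loc[shared].clip(lower=1e-6), b.loc[shared].clip(lower=1e-6),
               s=10, alpha=0.6)
    lim = [1e-6, max(a.max(), b.max()) * 2]
    ax.plot(lim, lim, color="grey", lw=0.8)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(f"{label_a} (amol/µg)")
    ax.set_ylabel(f"{label_b} (amol/µg)")
    fig.tight_layout()
    return fig
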