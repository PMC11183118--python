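"""Spike-in identification, library-size estimation and amol/µg normalization.

Synthetic spike-in RNAs of known molar amount (amol per µg of total RNA) are
added before oxidation. Methylated panel members survive oxidation and anchor
the library size factor (reads per amol/µg); unmethylated members are depleted
by oxidation and define the maximum expected background survival, from which
the enrichment cutoff for calling is derived.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AVOGADRO = 6.02214076e23


@dataclass
class SpikeInPanel:
    """Panel of spike-in species: id, sequence, methylation flag, amount."""

    ids: list[str]
    sequences: list[str]
    methylated: list[bool]
    amounts: list[float]  # amol per µg total RNA
    _lookup: dict = field(default=None, repr=False, compare=False)  # type: ignore

    def __post_init__(self):
        n = len(self.ids)
        if not (len(self.sequences) == len(self.methylated) == len(self.amounts) == n):
            raise ValueError("panel columns must have equal length")
        if len(set(self.sequences)) != n:
            raise ValueError("panel sequences must be unique")
        if not any(self.methylated):
            raise ValueError("panel needs at least one methylated member")
        if any(a <= 0 for a in self.amounts):
            raise ValueError("panel amounts must be positive")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "sequence": self.sequences,
            "methylated": [int(m) for m in self.methylated],
            "amol_per_ug": self.amounts,
        })

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpikeInPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(df["id"].tolist(), df["sequence"].str.upper().tolist(),
                   df["methylated"].astype(bool).tolist(),
                   df["amol_per_ug"].astype(float).tolist())

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def _build_lookup(self) -> dict:
        # exact sequences first, then all 1-substitution neighbors; earlier
        # panel members win ties and exact matches are never overwritten
        table: dict[str, tuple[str, int]] = {}
        for sid, seq in zip(self.ids, self.sequences):
            table.setdefault(seq, (sid, 0))
        for sid, seq in zip(self.ids, self.sequences):
            for i in range(len(seq)):
                for b in "ACGT":
                    if b == seq[i]:
                        continue
                    neigh = seq[:i] + b + seq[i + 1:]
                    if neigh not in table:
                        table[neigh] = (sid, 1)
        return table


def match_spikein(insert: str, panel: SpikeInPanel) -> str | None:
    """Panel member of equal length within Hamming distance 1, else None.

    Substitutions only (no indels); ties go to the fewest mismatches, then to
    panel order.
    """
    if panel._lookup is None:
        panel._lookup = panel._build_lookup()
    hit = panel._lookup.get(insert)
    return hit[0] if hit else None


@dataclass
class SizeFactor:
    """Reads per (amol/µg) for one library, with the per-spike-in ratios used."""

    value: float
    ratios: dict[str, float]


def size_factor(counts: Mapping[str, float], panel: SpikeInPanel,
                aggregator: str = "pooled") -> SizeFactor:
    """Library size factor from concentration-normalized methylated spike-ins.

    The default ``pooled`` estimator, total methylated spike-in reads divided
    by total methylated amount, weights each member by its read count and so
    is not dominated by the Poisson noise of the rarest panel member (which an
    unweighted mean of the per-member count/amount ratios is, when amounts
    span orders of magnitude). ``arithmetic`` and ``geometric`` means of the
    per-member ratios are available as alternatives.
    """
    meth = [(sid, amt) for sid, m, amt in
            zip(panel.ids, panel.methylated, panel.amounts) if m]
    ratios = {sid: counts.get(sid, 0.0) / amt for sid, amt in meth}
    vals = np.array(list(ratios.values()), dtype=float)
    if not (vals > 0).any():
        raise ValueError("normalization impossible: all methylated spike-in counts are zero")
    if aggregator == "pooled":
        s = sum(counts.get(sid, 0.0) for sid, _ in meth) / sum(a for _, a in meth)
    elif aggregator == "arithmetic":
        s = float(vals.mean())
    elif aggregator == "geometric":
        pos = vals[vals > 0]
        s = float(np.exp(np.log(pos).mean()))
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    return SizeFactor(float(s), ratios)


def normalize(raw_count, sf: SizeFactor | float):
    """Convert raw read counts to amol per µg total RNA."""
    s = sf.value if isinstance(sf, SizeFactor) else float(sf)
    if s <= 0:
        raise ValueError("size factor must be positive")
    return raw_count / s


def depletion_cutoff(ratios: Sequence[float]) -> float:
    """Mean + sample SD of the ox/unox ratios of the unmethylated spike-ins."""
    r = np.asarray(list(ratios), dtype=float)
    if r.size < 2:
        raise ValueError("need at least two unmethylated spike-in ratios")
    return float(r.mean() + r.std(ddof=1))


def molecules_per_cell(amol_per_ug: float, pg_total_rna_per_cell: float) -> float:
    """Convert a normalized expression value to molecules per cell."""
    if amol_per_ug < 0 or pg_total_rna_per_cell < 0:
        raise ValueError("inputs must be non-negative")
    return amol_per_ug * 1e-18 * AVOGADRO * pg_total_rna_per_cell * 1e-6


def spikein_counts_tsv(counts: Mapping[str, float], panel: SpikeInPanel,
                       path: str | Path, total_reads: int | None = None) -> None:
    df = panel.frame[["id", "methylated", "amol_per_ug"]].copy()
    df["count"] = [counts.get(sid, 0.0) for sid in panel.ids]
    if total_reads:
        df["fraction_of_library"] = df["count"] / total_reads
    df.to_csv(path, sep="\t", index=False)
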