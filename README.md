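# mimeseq

Analysis of **mime-seq** experiments — miRNome profiling of a chosen cell type
inside a mixed population via cell-type-restricted 2'-O-methylation of miRNA
3' ends followed by periodate-oxidation-selective small RNA cloning — plus a
synthetic generator of the whole assay so every stage is testable against
ground truth.

## Who this is for

Groups running spike-in-normalized small RNA-seq with paired oxidized (ox) and
untreated (unox) libraries, who need to go from raw barcoded FASTQ files to:

- per-miRNA expression in **amol per µg of total RNA** (anchored on methylated
  spike-ins of known molar amounts),
- per-miRNA **methylation fractions** (`% ox/unox`) and methylation **rates**
  over an induction timecourse, and
- **cell-type-specific miRNA calls** in cell mixtures, with false-positive
  bookkeeping against a pure reference population.

## The method in brief

Reads are laid out `[4 nt][insert][UMI₆][sRBC₅][3' adapter]`. The adapter is
located by an end-gap-free affine alignment (match +1, mismatch −1, gap open
−2, extend −1; score normalized by adapter length, cutoff 0.9); barcode and
UMI are read off upstream of it, and inserts are trimmed, quality- and
length-filtered (≥18 nt). Spike-in reads are matched within one substitution
and removed; the library size factor *s* (reads per amol/µg) is the pooled
count/amount ratio of the methylated spike-ins, and expression is `count/s`.

Remaining inserts are mapped by **maximal exact prefix** over both strands of
a transcriptome built from merged pre-miRNA contigs; the unmatched 3' suffix
is a non-templated tail, and the number of co-optimal placements is NH. A read
counts toward a mature miRNA when its templated 5' end is within ±5 nt of the
annotated 5' end and its 3' end exceeds the annotation by ≤5 nt (isomiRs sum
into their parent; each placement adds 1/NH).

For an ox/unox pair, `pct_ox_unox = 100·ox/unox` estimates the methylated
(cell-of-interest) fraction of each expressed miRNA (floor: unox > 0.5
amol/µg). Cell-specific miRNAs in a mix must additionally rank in the top 98%
of cumulative reads of the mix's oxidized library and exceed an enrichment
cutoff of mean + SD of the unmethylated spike-ins' ox/unox ratios — the
maximum expected depletion of an unmethylated species.

See `docs/methods.md` for the model details, generator defaults, numerical
conventions and known limitations.

## Worked example

Simulate a mixing experiment (a pure methyltransferase-expressing population
plus a 1% mix, default study conditions: 60 miRNAs, one specific marker
miRNA, 3×10⁵ reads/library) and analyze it:

```sh
mimeseq simulate -o demo --seed 7 --kind mixing --ratios 1.0,0.01
mimeseq analyze  -c demo/run.yaml
mimeseq report   -c demo/run.yaml
```

which prints:

```
== attrition ==
mix_1_unoxidized: 298377/300000 ok, 7272 spike-in, 285898 mapped
mix_1_oxidized: 218180/219487 ok, 5368 spike-in, 209048 mapped
mix_0.01_unoxidized: 298468/300000 ok, 7432 spike-in, 285831 mapped
mix_0.01_oxidized: 8371/8417 ok, 5350 spike-in, 2951 mapped
== enrichment cutoffs (ox/unox) ==
mix_1: 0.0502
mix_0.01: 0.0275
== calls in mix_0.01 == 1 called, 0 false positives
mir-5
```

Reading this: parsing keeps ~99.5% of reads (the rest are barcode/adapter
failures); ~2.5% of clean inserts are spike-ins. The oxidized pure library
retains most reads (the miRNome is methylated), while the oxidized 1%-mix
library collapses to ~8k reads — oxidation destroyed the 99% of molecules
made by methyltransferase-free cells. One miRNA passes all three call gates
in the 1% mix with zero false positives: `mir-5`, which is exactly the
planted cell-type-specific marker in this simulation (see the `specific`
column of the ground-truth table `demo/mirnome.tsv`). Per-library expression
tables, counts,
tails, spike-in QC and `report.json` land under `demo/results/`.

The same API is importable (`mimeseq.run_experiment`,
`mimeseq.methylation_fraction`, `mimeseq.call_specific`, ...) for notebook
use; `mimeseq.plotting` has helpers for the standard displays.

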