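# Methods

## The assay being modeled

mime-seq identifies the miRNAs of a chosen cell type inside a mixed population
by genetically restricting a 3'-terminal 2'-O-methyltransferase to that cell
type. Total small RNA is extracted from the mixture, synthetic spike-ins of
known molar amounts are added, and the sample is split: one half is treated
with sodium periodate (NaIO4), the other is not. Oxidation destroys the
3'-terminal 2',3'-diol of unmethylated RNAs and blocks their 3'-adapter
ligation, so the oxidized library is strongly enriched for molecules that were
2'-O-methylated — i.e. molecules made in the cell type of interest. The
package implements everything downstream of sequencing: read decomposition,
spike-in normalization, exact-prefix mapping, isomiR-aware counting, and the
paired oxidized/untreated ("ox/unox") statistics, plus a synthetic generator
of the whole assay so that each stage can be tested against ground truth.

## Read decomposition

Reads follow the layout `[4 random nt][insert][UMI 6 nt][sRBC 5 nt][3'
adapter]` (sRBC = sample barcode, adjacent to the adapter; a configuration
flag swaps the UMI/sRBC order). The expected adapter
(`AGATCGGAAGAGCACACGTCT` by default) is aligned to each read with an
end-gap-free affine alignment: match +1, mismatch −1, gap open −2, gap
extension −1, terminal gaps free on both sequences. A gap of length g costs
2+(g−1), the same convention as Biopython's `PairwiseAligner`, which the test
suite uses as an independent cross-check of the scoring; placement and score
are also verified against a scalar brute-force DP on randomized reads. The
alignment score is divided by the adapter length; reads below 0.9 are
discarded as `no_adapter`. With a 21-nt adapter the 0.9 cutoff admits exactly
one substitution ((20−1)/21 ≈ 0.905) or one short gap.

The 11 nt upstream of the adapter are interpreted as UMI+sRBC; reads whose
sRBC differs from the expected barcode at any position are `wrong_srbc`.
The remaining 5' sequence is the insert: it must be ≥18 nt before and after
trimming 4 nt from its start (`too_short` otherwise), and it must pass a
fastp-default-equivalent quality rule (≤40% of bases below Q15, ≤5 Ns;
`low_quality` otherwise). The five statuses partition every read. UMIs are
recorded and carried through but not used to deduplicate reads — counting
operates on read counts, as UMI collapsing is not part of the quantification
procedure here.

For throughput, reads containing the adapter verbatim take a fast path (an
exact occurrence attains the maximal possible score at the leftmost placement,
so it coincides with the DP optimum under the smallest-start tie-break); all
other reads go through a vectorized batch DP.

## Spike-in normalization

Spike-in inserts are identified by equal-length Hamming distance ≤1 matching
(substitutions only) against the panel and removed before mapping. The
library size factor (reads per amol/µg) is estimated from the methylated
panel members as the pooled ratio Σcounts/Σamounts. The pooled estimator is
count-weighted and therefore Poisson-optimal; an unweighted arithmetic mean of
the per-member count/amount ratios (available via
`size_factor(..., aggregator="arithmetic")`, as is a geometric mean) is
dominated by the counting noise of the rarest panel member when amounts span
orders of magnitude, which at desk-scale depths visibly distorts downstream
ratios. Expression is reported as `count / size_factor` in amol per µg of
total RNA. `molecules_per_cell` converts amol/µg to molecules using Avogadro's
number and a per-cell total RNA content in pg.

## Mapping and counting

The transcriptome is built by excising every pre-miRNA interval (plus an
optional flank) from the genome; intervals overlapping after flanking merge
into a single contig carrying all of their lifted annotations. Inserts are
mapped by their longest exact prefix (no mismatches or indels) over both
strands of the contigs, seeded by an 18-mer hash and extended; placements
achieving the maximal prefix length are all reported, their count is NH, and
the unmatched 3' suffix is the non-templated tail. Inserts whose maximal
prefix is shorter than 18 nt are unmapped. An optional SAM emission encodes
tails as 3' soft clips.

A mapped insert counts toward a mature miRNA when, on the same strand, its
templated 5' end lies within ±5 nt of the annotated 5' end and its templated
3' end exceeds the annotated 3' end by at most 5 nt — so isomiRs sum into
their parent miRNA and tails never disqualify a read. A read qualifying for
more than one mature (possible on merged contigs) is assigned only to the
nearest-5'-end feature, ties broken by coordinate then name, preventing
double counting. Each qualifying placement adds 1/NH. Pre-miRNA counts use
plain strand-specific overlap (≥1 nt). Tail tables are unweighted read
counts per (feature, tail) — descriptive statistics where NH down-weighting
would obscure raw evidence.

## Ox/unox statistics and calling

For each ox/unox pair, every miRNA whose unoxidized expression strictly
exceeds the floor (0.5 amol/µg default, matching a mouse-style panel; 0.01
for human-style data) gets `pct_ox_unox = 100·ox/unox`, the estimated
percentage of its molecules that were methylated. Ratios are not capped at
100%; sampling noise legitimately produces values above it. Methylation rates
are the pct slope between 6 h and 12 h of induction. Note an identifiability
caveat baked into saturating kinetics m(t) = M·(1 − e^(−kt)): the 6–12 h
slope is monotone in k only below k = ln2/6 ≈ 0.116 h⁻¹; beyond the
plateau's onset, faster k means a *smaller* late slope. Rate comparisons are
therefore meaningful in the pre-saturation regime, which is why the window
sits early in the timecourse.

Cell-specific miRNAs in a mix are called by three gates: (1) expressed in the
unoxidized mix (floor above), (2) ranked within the smallest descending
prefix reaching 98% of cumulative reads in the mix's own *oxidized* library
(ties at the boundary broken by name; the boundary member is included), and
(3) ox/unox above an enrichment cutoff set as mean + sample SD (n−1) of the
ox/unox ratios of the unmethylated spike-ins, which mark the maximum expected
survival of an unmethylated species. Panels without unmethylated members
(human-style) require a user-supplied cutoff. Note that mean+SD is not
coordinate-wise monotone in the ratios — raising a below-mean ratio shrinks
the SD faster than it lifts the mean — which is a property of the estimator,
not a bug. False positives are calls absent from the reference miRNome, which
is built from the *oxidized* pure population (the unoxidized one may contain
RNA from contaminating cells that oxidation removes).

## The synthetic assay generator

`simulate_experiment` emulates the full assay. What it models, with defaults
(all set once as study conditions, configurable via `SimConfig`):

- **miRNome**: 60 miRNAs with log-normal abundances (log-SD 1.5, matching the
  several-orders-of-magnitude dynamic range of real miRNomes). One cell-type-
  specific miRNA drawn at marker-like high abundance (log-mean shifted by
  +3.0, log-SD 0.3), emulating canonical markers that top their cell type's
  miRNome. Reference contigs are random 110-mers embedding one hairpin with
  1–2 mature annotations on either strand; contigs are rejection-sampled so
  no 18-mer recurs across contigs (unambiguous mapping by construction),
  except for optional duplicated families that create genuine NH=2
  multimappers.
- **Methylation kinetics**: single-exponential saturation
  m_i(t) = M_i·(1 − e^(−k_i t)) with plateaus M_i ~ U(0.55, 0.95) and rates
  k_i ~ U(0.04, 0.20) h⁻¹ (a 5-fold range), timepoints 0/6/12/24/48 h. In a
  mix with a fraction ρ of methyltransferase-expressing cells, shared miRNAs
  are methylated at ρ·m_i(t); specific miRNAs at m_i(t) with ρ-scaled
  abundance.
- **Oxidation**: independent per-molecule thinning. Methylated molecules
  always survive; unmethylated spike-ins survive with probability 0.02 (the
  `oxidation_leak`); unmethylated endogenous miRNAs survive at 0.1× that
  (0.002). The asymmetry implements the assay's empirical design premise that
  the unmethylated spike-ins bound the background survival of any
  unmethylated species from above — without it, a mean+SD cutoff on the
  spike-in ratios could not separate background at all.
- **Spike-ins**: a synthetic stand-in panel of 8 fixed 22-mers (4 methylated
  at 0.5/5/50/500 amol/µg, 4 unmethylated at 0.2/2/20/200), spanning ~3.4
  orders of magnitude, with an expected 2.5% read share.
- **Reads**: depth 3×10⁵ per library (the desk-scale stand-in for real
  sequencing depth; every analysis quantity scales with it), isomiR 5'/3'
  offsets ~ round(N(0, 0.8)) clipped to ±2 (so every insert stays ≥18 nt and
  truth comparisons stay exact), non-templated tails on 15% of miRNA reads
  (lengths 1–3, first base drawn to differ from the next templated base so
  tails are never absorbed into the mapped prefix), uniform substitution
  errors at 10⁻³/base, constant Q40 qualities (a degraded mode emits a
  fraction of Q2 reads to exercise the quality filter).

What it does **not** model: ligation bias, PCR duplication structure beyond
UMIs, position- or motif-dependent error profiles, partial oxidation
time-dependence, RNA degradation, or between-replicate biological variation.
Passing tests therefore demonstrate the correctness of the computational
pipeline under idealized sampling, not robustness to those real-data
artifacts.

One structural consequence of the 2% spike-in leak default: at a 1% mixing
ratio a broadly shared miRNA has ox/unox ≈ 0.01·m + leak ≈ 0.01, below the
mean+SD cutoff, so under these conditions mix calls are essentially restricted
to truly cell-specific miRNAs. Partial recovery of shared miRNAs at 1% mixing
(as opposed to specific markers) requires a lower background leak than the
default models.

## Numerical and design choices

- Adapter DP tie-breaks: smallest start, then shortest interval; N matches
  nothing (always a mismatch); non-ACGTN characters are errors.
- The normalized adapter score divides by adapter length (placement-
  independent, bounded by 1).
- Mature assignment tie-breaks: nearest 5' distance, then lowest start
  coordinate, then name.
- `top_cumulative_set` guards the cumulative comparison with a 1e-12 relative
  tolerance so float roundoff cannot drop the boundary member.
- All analysis stages are deterministic; the only randomness is the
  generator's, driven by one seed per experiment with fixed per-library
  substreams, so reruns are byte-identical.
- Degenerate inputs: all-zero expression tables raise; size factors require
  at least one nonzero methylated spike-in count; the depletion cutoff
  requires ≥2 ratios; Spearman concordance requires ≥3 shared miRNAs.

## Test scales

Unit and property tests run on small instances (10³–10⁵ reads). The deeper
checks use the sizes at which their statistical claims are stated: spike-in
recovery and counting round-trips at 3×10⁵ reads, methylation-fraction
recovery (mean absolute error < 2 percentage points across planted fractions
0–1) at 10⁶ reads per library with zero leak, and end-to-end calling at the
default depth over 20 seeds per arm (a specific miRNA at 1/1000 cells must be
called in ≥18/20 runs; a methyltransferase-free control must yield zero calls
in ≥18/20 runs). These sizes were chosen as the package's desk-scale study
conditions; the per-run statistical behavior was analyzed at the counts level
before the defaults were frozen.
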