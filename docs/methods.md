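# Methods

This note documents the statistical models behind `mirprot`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions.

## Proteomics differential expression

The LFQ stage mirrors the standard Perseus workflow on a MaxQuant
protein-groups table.

**Cleaning.** Rows flagged `Reverse` (decoy), `Potential contaminant` or
`Only identified by site` are removed; zero LFQ intensities are treated as
missing. Counts dropped per reason are logged.

**Valid-value filter.** The default retains a protein iff it has at least
`min_valid` (default 3) observed values in *at least one* group of 5. This
is the Perseus "at least N in one group" convention: it keeps proteins that
are entirely absent in one condition — exactly the candidates MNAR
imputation exists for. A strict mode (`rule="both"`) requiring the quota in
every group is provided for users who prefer only fully-quantified
proteins.

**MNAR imputation.** Missingness in LFQ data is concentrated at low
abundance (left-censoring), so missing values are replaced by draws from a
narrowed, downshifted normal distribution computed per sample column:
observed mean `m` and sd `s`, imputed values `~ N(m − downshift·s,
(width·s)²)`. Defaults: width 0.3; downshift 1.8 for the iron-exposure
comparison and 1.75 for the transformation comparison (selected by the
pipeline's `comparison` field). Imputation never alters observed cells
(asserted bit-exactly in tests) and is seeded. A column needs ≥ 2 observed
values; fewer is an error rather than a silent guess. Imputation is per
sample column (the Perseus default); no global-distribution mode is
offered.

**Testing and tiering.** Per protein, a two-sided Welch t-test (unequal
variances, Welch–Satterthwaite df) compares the two groups on the imputed
log2 scale. The degenerate case of zero variance in both groups with equal
means returns p = 1 by convention. The **z-score** is the standardization
of the per-protein mean log2 ratio across all quantified proteins
(`z = (log2fc − mean)/sd`, sample sd) — the conventional volcano usage; the
source workflow does not state its exact formula, so this choice is
documented prominently here and is the package's own. The **ratio** of
treatment over control defaults to the geometric convention
`2^(mean log2 difference)`; an arithmetic mean-of-raw-intensities mode is
available since spreadsheet workflows often compute it that way. Tiers:

* significant — p < 0.05 and |z| > 1 (the combined variance/fold filter
  used instead of BH correction, which costs sensitivity at n = 5);
* differential — significant and ratio ≥ 2 or ≤ 0.5;
* top — significant and ratio ≥ 4 or ≤ 0.25.

The chain top ⊆ differential ⊆ significant holds by construction and is
property-tested.

**CV summary.** Per protein per group, CV = sd/mean over observed raw
intensities; the average and median across proteins are reported in
percent. Note the sample CV at n = 5 underestimates the population CV by
the c4 factor (≈ 0.94); tests compare generator output against the
c4-adjusted expectation.

## Power design

For a two-sided, unpaired, equal-n two-sample t-test, the power at effect
size d is computed exactly from the noncentral t distribution with
df = 2n − 2 and noncentrality d·√(n/2), counting both rejection tails. The
minimal detectable effect inverts this by Brent root-finding (|Δd| < 1e−9).
At n = 5, α = 0.05, power 0.9 this gives d = 2.348. Two independent checks
are kept in the tests: statsmodels' solver and a seeded Monte-Carlo power
simulation.

The conversion from d to a raw-scale fold change assumes log-normal
intensities: `FC = exp(d·sdln)` with `sdln = √(ln(1+cv²))` (≈ cv for small
cv). The source workflow does not state its conversion arithmetic, so the
band implied by the four observed group CVs (≈ 1.6–1.8) is asserted
loosely by design.

## miRNA differential expression

Duplicate feature ids (arrays repeat some snoRNA/miRNA probes) are
collapsed by per-sample median. Each miRNA is tested with an
equal-variance two-sample t-test by default — at n = 3 per group the
pooled-variance test is the array convention; Welch is available by flag.
Ratios are geometric (from mean log2 intensities). Fold changes are
reported in the signed convention: ratio ≥ 1 → +ratio, ratio < 1 →
−1/ratio — a strictly monotone bijection from (0,∞) onto (−∞,−1] ∪ [1,∞).

Selection defaults to raw p < 0.05 with BH-FDR always reported alongside
(`use_fdr=True` switches selection to the adjusted values). The default
follows the workflow actually applied to the printed tables, which contain
rows that are non-significant after adjustment; the stricter FDR selection
is one flag away. Tiers: twofold (ratio ≥ 2 or ≤ 0.5) and fourfold (≥ 4 or
≤ 0.25), each requiring the p criterion; fourfold ⊆ twofold always.

Locus annotation uses a lookup assembled from the packaged tables
(miRNA → cytoband, cytoband → nearest common fragile site); ids are
matched case-insensitively with any `hsa-` prefix stripped, unknown ids
annotate to null rather than erroring. Cluster summaries use cytoband
*prefix* matching so that "14q32" aggregates 14q32.2 and 14q32.31.

## qPCR quantification

Livak 2^−ΔΔCT with amplification efficiency fixed at exactly 2 (the
method's assumption; no standard-curve efficiency estimation). Per sample,
ΔCT = CT_target − CT_reference; groups are aggregated by the arithmetic
mean of ΔCT; ΔΔCT refers the treated group to the calibrator. The result
is exactly invariant to adding a constant to all CTs of a sample (the
reference cancels it), which is asserted as an identity. Percent change is
reported as (1−fold)·100 "reduction" below 1 and (fold−1)·100 "increase"
above.

## Integration (inverse-expression pairing)

Commercial target filters are replaced by a plain TSV target map
(miRNA id, gene symbol, evidence ∈ {experimental, high, moderate}). An
edge survives iff both endpoints pass their fold cutoffs (defaults 4 and
4) and moved in opposite directions. Gene matching is case-insensitive
exact symbol match; no alias resolution (a documented limitation). The
output is always a subset of the map, sorted (miRNA, gene), and raising a
cutoff can only shrink it — both property-tested. `common_targets`
intersects per-miRNA target sets; `summarize_by_locus` counts distinct
miRNAs and genes per cytoband.

The packaged map `target_map_fig5_synthetic.tsv` is a synthetic
reconstruction constrained by the printed network facts (7, 3 and 7
targets for miR-432-5p, miR-127-3p, miR-138-5p; PAX8 common to all three;
ALDH1A2 under miR-138-5p); filler genes come from the packaged 28-protein
table. It supports fixture-level checks only and makes no knowledge-base
equivalence claim.

## Motif scanning

Ungapped sliding-window counting of exact base matches for the three EVI1
sites, deliberately replacing gapped alignment: the quantities of interest
are match fractions of 9–11-mers, which ungapped scanning captures
directly and reproducibly. Forward strand by default (promoter orientation
is the user's to fix); reverse-strand hits count matches of the
reverse-complemented motif against the forward sequence. 'N' never
matches. Coordinates are 0-based, half-open, relative to the scanned
window; ties in match count break by ascending position. `upstream_window`
takes the final W bases of an upstream-region record (default 5000) and
returns shorter records whole with a warning.

## Synthetic data

The generators reproduce the statistical structure the analysis assumes,
with ground truth for recovery tests:

* **Intensities** are log-normal: per feature a baseline log2 mean is drawn
  from N(25, 2) (a typical LFQ log2-intensity scale; the raw-intensity
  distribution of real LFQ data is not specified anywhere authoritative,
  log-normality is this package's modelling assumption) and replicates
  scatter around it with log2 sd `√(ln(1+cv²))/ln 2` — the exact
  log-normal CV relation. Defaults: 5 replicates/group (3 for arrays),
  cv = 0.22 (the observed 20–25% range), true effects on a fraction
  `de_fraction` of features, |log2FC| uniform on [1, 7] (2- to ~100-fold)
  with random sign.
* **Missingness** (LFQ only) is logistic in the true log2 intensity,
  anchored at a quantile of the realized intensity distribution:
  P(miss) = expit(−steepness·(x − anchor)). The mechanism behind
  downshifted imputation is left-censoring; the logistic form is the
  standard smooth model for it. An anchor quantile of 0.075 with slope 1.5
  realizes ≈ 10% overall missingness, the level used in the recovery
  tests. Quantile 0 disables missingness.
* **Target maps** plant a requested number of truly-inverse
  (miRNA down/protein up or vice versa) edges plus uniform random decoys.
* **CT tables** follow the doubling model: target CT = the sample's
  reference CT + a fixed assay offset − log2(fold) + Gaussian cycle noise,
  so zero-noise tables invert exactly through 2^−ΔΔCT.
* **Promoters** are uniform ACGT with a motif copied in after mutating
  exactly k distinct positions.

One master seed per configuration; per-stage substreams are spawned via
`numpy.random.SeedSequence`, making every generator bit-reproducible.

What the generators do **not** emulate: peptide-level structure,
between-run normalization drift, probe-level array noise, correlated
missingness across samples, miRNA seed-sequence biology, or genomic
sequence composition. Passing recovery tests therefore demonstrate the
statistical machinery is correct under the stated model, not that the
model captures every pathology of real instruments.

## Problem sizes and numerics

Tests and examples run at 200–4000 features and 10⁴–10⁵ Monte-Carlo
replicates — sizes chosen so every statistical assertion has comfortable
Monte-Carlo headroom (tolerances are set at 3–5 standard errors of the
quantity under test). Root-finding tolerances are 1e−9 on d; identity
assertions (round-trips, offset invariance, observed-cell preservation)
are exact or at 1e−12. TSV writers emit floats with `%.17g` and readers
parse with round-trip precision, so writer/reader cycles are bit-exact.

## Known limitations

* Gene matching by symbol only; aliases and ids are not resolved.
* The miRNA/protein pairing is correlational gating, not target
  prediction; evidence levels are carried through, never weighted.
* No between-run normalization of LFQ intensities (out of scope; inputs
  are assumed already LFQ-normalized).
* Equal-variance miRNA t-test at n = 3 is a convention, not an inference
  guarantee; Welch is available but has little power at that n.
* The fixture-level counts reproduce printed summaries; full-dataset
  counts (total identified/quantifiable proteins, full DE lists) require
  the deposited raw data and are outside the package's scope.
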