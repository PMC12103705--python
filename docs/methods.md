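# Methods

## The problem

Histone deacetylase inhibitors (HDACi) raise global histone acetylation and
reshape transcription, but individual genes respond in both directions.
`epiresponse` implements and tests the hypothesis that the *pre-treatment*
H3K27ac profile around a gene predicts the *direction* of its expression
change after treatment.  The pipeline summarises each gene's chromatin
context as 21 binned signal values, labels genes up/down from paired pre/post
expression, and benchmarks classifiers that map the bin profile to the
response direction.

## The 21-bin genic scheme

For each gene with transcribed region `[start, end)` (0-based, half-open)
and strand-aware TSS:

* **P1..P10** — the 2 kb window immediately upstream of the TSS, split into
  ten 200 bp bins, ordered 5'→3' (P1 is furthest upstream).
* **TSS** — the single transcription-start base.
* **GB1..GB10** — the transcribed region split into ten near-equal bins;
  edges sit at `start + floor(k·L/10)`, so widths differ by at most 1 bp.

The TSS base is also the first base of GB1: the bins are features of the
locus, not a partition, and the 1 bp overlap is deliberate — both the
single-nucleotide TSS definition and the "entire transcribed region" gene
body are kept literally.  On the minus strand the layout mirrors genomically
while labels keep their 5'→3' meaning.  Mirror symmetry through a pivot is
exact whenever `L` is divisible by the bin count; for other lengths the
floor-edge rule fixes the remainder bases deterministically from the genomic
left, which breaks exact reflection symmetry by at most 1 bp per edge.

Representative coordinates for multi-transcript genes are the union span
with the most-5' TSS; a user-supplied gene→TSS table can override this
(an override re-anchors the transcribed region at the given base).  Genes
shorter than `min_length` (default 200 bp, always at least the bin count)
are dropped, as are genes whose promoter window leaves the chromosome.

## Bin signal and normalization

The bin signal is the **area of the per-base coverage track** over the bin
(sum of per-base coverage).  This differs from counting aligned reads per
bin: it is exactly reproducible from a standard bedGraph/bigWig file and
has no boundary-read ambiguity.  Areas are computed as correctly-rounded
sums (`math.fsum`) of `value × overlap` products, so results do not depend
on how the track happens to be split into segments.

TPM normalization mirrors the expression-side convention: per-kb rates
`raw / (len/1000)` rescaled so one sample's bins total 1e6.  The denominator
runs over *all* 21 × n_genes bins of the sample, preserving relative bin
shape.  The 1 bp TSS bin consequently carries a ×1000 per-kb rate inflation;
this is a property of the formula and is retained (per-feature
standardization absorbs it before any model sees the data).  Spike-in
correction divides the whole matrix by the count of reads aligned to the
exogenous (e.g. Drosophila dm6) genome, after which the grand-sum identity
no longer holds — intentionally, since preserving global occupancy shifts
is the point of spike-ins.

## Response labels

`lfc = log2(TPM_treated + c) − log2(TPM_untreated + c)` with pseudocount
`c = 1` (configurable) to bound ratios for unexpressed genes.  The top N
and bottom N genes by lfc form the up/down classes (N defaults to 1000);
ties at a boundary break lexicographically by gene id, and the up set is
taken before the down set so the classes are always disjoint.  Everything
else is "unchanged".  No dispersion model or significance test is applied —
the method is a ranking, and an optional minimum-expression filter is off
by default.  Discordant genes between two cohorts use strict thresholds on
the pseudocounted fold `2^lfc` (> 3 in one and < 1/3 in the other).

## Benchmarking

Feature subsets: promoter (10), TSS (1), gene body (10), all (21), columns
in 5'→3' order.  Model families and scores:

| family | model | score | notes |
|---|---|---|---|
| SVM | RBF kernel, C = 1, gamma = "scale" | signed decision margin | no probability calibration needed for AUC |
| RF | random forest, 100 trees | class-1 probability | 100 trees (the library default); doubling to 500 left mean CV AUCs unchanged to the third decimal at these problem sizes while multiplying fit cost |
| GB | gradient boosting, 100 trees, depth 3, lr 0.1 | class-1 probability | |

Evaluation is stratified five-fold cross-validated ROC AUC with a fixed,
configurable shuffle seed (default 42).  Per-feature standardization is fit
on training rows only — inside each fold, or on the whole training cohort
for transfer — so the scaler never sees test rows.  Transfer aligns columns
by bin label and applies the training cohort's scaler to the test cohort,
with no further cross-cohort harmonization.  Reported AUCs are CV means
(per-fold values are kept in the long-format output).

`compare_discordant_profiles` z-scores each gene's 21-bin profile (mean 0,
sd 1 across bins; constant rows map to zeros), then reports per bin ×
gene-set × cohort the median/quartiles plus a two-sided Mann-Whitney U
between cohorts.  Benjamini-Hochberg q-values across the 21 bins are
available but off by default, matching outputs that report no test.

## The synthetic cohort model

Per gene `g` with class `c_g` (up = −½, down = +½), the per-base density of
bin `b` is

    density[g,b] = exp(baseline[b] + c_g·delta[b] + sigma·eps[g,b]),  eps ~ N(0,1)

so `delta` is the per-bin down-minus-up log-mean shift.  Log-normal
marginals reflect that ChIP-seq densities are non-negative and
right-skewed, and make the optimal ranking analytically tractable: on log
scale the classes are homoscedastic Gaussians, giving the Bayes AUC
`Φ(‖delta‖ / (sigma·√2))` for independent bins (`bayes_auc`).  The raw bin
value is density × bin width — the exact area of a constant-height track
over the bin — so the per-kb TPM rate is `1000 × density` and gene-length
variation cancels out of the features.  Bins are independent by default;
`rho` adds exchangeable log-scale correlation for robustness experiments
(the closed form then no longer applies and `bayes_auc` refuses).

Defaults and why:

* `n_genes = 2000` — two balanced classes of 1000, the top/bottom-N sizes
  used throughout.
* `sigma = 0.5` — moderate log-scale noise; the implied coefficient of
  variation (~53%) is in the range seen for replicate ChIP-seq bin signals.
* `baseline` — a metagene shape rising through the promoter, peaking at the
  TSS, decaying along the body, i.e. a typical active-gene H3K27ac profile.
* `lfc_effect = 2.0`, `lfc_sd = 0.5` — planted |log2 FC| well above its
  spread, so expression-derived top-N labels recover ≥ 95% of the planted
  classes; untreated TPM is log-normal (meanlog 3, sdlog 1).
* gene lengths uniform in 1–50 kb on one synthetic chromosome, loci spaced
  by more than twice the promoter window so no two loci can overlap.

Preset effect profiles (`low_dose`, `mid_dose`, `high_dose`) encode the
qualitative dose response: down-regulated genes carry more upstream
H3K27ac at every dose; in the gene body the same holds at mid/high dose
but reverses at low dose.  Magnitudes taper linearly away from the TSS
(0.03→0.25 across promoter and body bins; TSS 0.30, or 0.15 for low dose;
high dose scales mid by 1.15).  They are documented constants chosen so
the attainable cross-validated AUC lands in the 0.71–0.89 range
characteristic of this class of predictor — not fitted to any dataset.
With them, Bayes/SVM-CV AUCs are roughly 0.84/0.80 (low), 0.86/0.82 (mid)
and 0.89/0.86 (high) at n = 2000.

**Exact round trip.**  `render_track` emits a piecewise-constant bedGraph
whose area over every bin reproduces the raw matrix bit-for-bit.  The TSS
base lives inside GB1, so GB1 is rendered as the TSS base at the TSS
density plus a remainder density chosen to conserve GB1's total area
(clipped at zero in the astronomically unlikely case the TSS value exceeds
the whole GB1 area).  Because both the generator and `quantify_bins`
compute bin values as `fsum` of identical products, equality survives
bedGraph serialization and segment merging.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level sampling noise, fragment-length and GC
effects, mappability gaps, input-control background, enhancer signal
outside the 2 kb window, correlated multi-gene domains, and any real
coupling between chromatin state and expression beyond the planted class
shifts.  Synthetic results validate the machinery and its statistical
calibration, not the biological effect sizes.

## Numerical choices

* Intervals are 0-based half-open everywhere internally; GTF's 1-based
  inclusive coordinates are converted at the boundary.
* Bin areas: `math.fsum` (correctly rounded, split-invariant).  Exactness
  tests use integer-valued tracks, where per-base summation is exact.
* TPM grand sum holds to 1e-9 relative; all-zero matrices pass through
  with a warning instead of dividing by zero.
* Z-scoring uses the population sd; constant rows map to zeros.
* Stratified folds, model seeds and the generator are all driven by
  explicit integer seeds; reruns are byte-identical.
* Degenerate inputs fail fast with named errors: overlapping track
  intervals, single-class label sets, classes smaller than the fold count,
  subset mismatches in transfer.

## Problem sizes in the test suite

Statistical acceptance checks run at the study conditions (n = 2000,
balanced classes) with 20 seeds for calibration/monotonicity/transfer
consistency, 6–8 seeds for effect-recovery and subset-preference means;
structural and oracle checks use 30–1000 genes.  These sizes give standard
errors of CV-AUC means of ~0.002–0.005, an order of magnitude below every
tolerance asserted.

## Known limitations

* The bin signal is track area, not a read count; pipelines that count
  boundary-spanning reads once per bin will differ slightly.
* One representative TSS per gene; alternative promoters are out of scope.
* The discordant-gene comparison reports rank tests per bin without
  modelling inter-bin correlation.
* `bayes_auc` covers independent bins only.
* No enrichment analysis, peak calling, alignment or isoform handling.
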