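# Methods

This note documents the models, defaults and numerical choices behind
`coresat`, and what the synthetic test bed does and does not establish.

## Preprocessing rules

Counts enter as taxon × sample integer tables. Two upstream filters are
applied before any statistic: (1) *singleton removal* — a taxon whose
total count across the whole dataset equals exactly 1 is dropped (a
per-dataset rule, not per-sample; a 1+1 split across two samples is
kept); (2) *species-OTU collapsing* — rows whose full seven-rank lineage
is identical, case-sensitively, and includes a species assignment are
summed into one OTU; rows without a species assignment pass through
unmerged, so homonymous species in different genera are never pooled.
Collapsing is integer arithmetic and conserves per-sample totals exactly.
Relative abundances (percent, columns summing to 100) are computed after
both filters.

## Core/satellite partitioning

Per group, a taxon's *distribution* d is the percentage of the group's
samples in which it has a positive count, and its *mean abundance* ā is
the mean percent relative abundance over those positive samples only
(absent samples do not dilute ā). The distribution–abundance relationship
is an OLS regression of log₁₀ ā on d; the abundance axis is
log-transformed because mean abundances span orders of magnitude and are
conventionally plotted on a log axis in this literature, and the choice is
recorded in each run's manifest. F is computed as (R²/1)/((1−R²)/(n−2))
with P from the F(1, n−2) upper tail. d is in percent units; this scales
the slope only, never R², F or P.

Core status is d ≥ threshold with the threshold **inclusive** and
defaulting to 75 %. Core sets are monotone-nested in the threshold, and
labels are invariant to taxon order and to per-sample count rescaling
(prevalence and relative abundance are both scale-free).

The log-normal goodness-of-fit of the core set takes log₁₀ ā, fits mean
and SD by sample moments, bins into k = max(4, ⌈√n⌉) equal-probability
bins of the fitted normal, merges adjacent bins until every expected count
is ≥ 1 (a no-op whenever n ≥ k), and reports χ² with df = bins − 3 (two
estimated parameters), floored at 1. Fewer than 8 core taxa flags the
result unreliable rather than raising, since the pipeline must still run
on small groups.

## Alpha diversity

Fisher's α is the implicit solution of S = α ln(1 + N/α), found by
bracketed Brent root search on α ∈ (10⁻¹⁰, 10¹⁰); every returned α
satisfies the defining equation to |residual| < 10⁻⁸. It is undefined at
S ≥ N (all-singleton limit) and computed on **unrarefied** counts, the
convention of the desktop ecology packages this stage mirrors. Shannon H′
uses natural-log units and is computed on counts rarefied without
replacement (multivariate hypergeometric per sample — the `rrarefy`
model) to a common depth defaulting to the minimum sample total; rarefied
column sums equal the depth exactly and rarefied counts never exceed the
originals. Group tests are Kruskal–Wallis omnibus plus pairwise
Mann–Whitney U with Bonferroni adjustment; samples where a metric is
undefined within a stratum (e.g. zero satellite reads) are excluded from
that stratum's test and logged.

## Community structure

Bray–Curtis dissimilarities are computed on percent relative abundances.
ANOSIM ranks all off-diagonal dissimilarities with mid-ranks for ties
(making R invariant under any order-preserving transform of the
distances), and estimates P by random relabeling with the
(1 + #{R\_perm ≥ R\_obs})/(1 + n\_perm) estimator — never exactly zero,
deterministic per seed. The default 9999 permutations is the convention of
the desktop packages; for small n an exact mode enumerates every distinct
assignment of the label multiset instead. Pairwise runs operate on each
pair's submatrix with P multiplied by the number of pairs and capped at 1.

SIMPER uses the identity that Bray–Curtis is additive over taxa for a
fixed sample pair: δᵢ(j,k) = |xᵢⱼ−xᵢₖ|/Σₗ(xₗⱼ+xₗₖ). Contributions are
means over all between-group pairs and therefore sum *exactly* to the mean
between-group dissimilarity (tested to 10⁻¹⁰). SIMPER runs on percent
relative abundances, matching the scale of the distance stage; note that
under compositional closure a change concentrated in one taxon necessarily
redistributes share to the others, so "one driver" patterns are cleanest
on an unclosed common scale.

PCoA double-centres −½D², takes the symmetric eigendecomposition, and
scales eigenvectors by √λ for positive eigenvalues. Negative eigenvalues
(non-Euclidean distances) are reported and their axes dropped — no
Lingoes/Cailliez correction, matching common practice for
visualization-grade ordination; percent variance is relative to the
positive-eigenvalue sum. Confidence ellipses use the group covariance
(ddof = 1): semi-axes √(λᵢ · χ²₂(0.95)) along the covariance eigenvectors,
with near-singular covariances flagged degenerate rather than raised.

## Hypothesis tests and multiplicity

All tests are two-sided. Mann–Whitney U reports min(U₁, U₂) and uses the
exact null distribution when n₁n₂ ≤ 400 with no ties, otherwise the
normal approximation with tie-corrected variance and continuity
correction; the two branches agree to < 0.01 in the regimes where both
apply. Kruskal–Wallis uses the tie-corrected H with a χ²(g−1) tail and
returns H = 0, P = 1 when every value is identical. One-way ANOVA is the
classical F = MS_between/MS_within; zero within-group variance with
unequal means is flagged (F = ∞, P = 0) rather than hidden. Bonferroni is
min(1, m·p); Benjamini–Hochberg is the step-up adjustment with downward
monotonicity enforcement, returned in input order, and is dominated
elementwise by Bonferroni. The heatmap-style CLR comparison exposes both
Kruskal–Wallis and ANOVA; the pipeline default is ANOVA on CLR values,
with the rank test one keyword away.

## Predicted-function stage

Contribution tables are long-form (sample, taxon, function, abundance)
records as emitted by metagenome-prediction tools. A function belonging to
k pathways contributes its full abundance to each — the standard
hierarchy-collapse convention, recorded in the manifest; unmapped
functions are excluded and counted. Stratification restricts contributions
to the taxa a partition labels core (or satellite) *before* aggregation
and renormalization, so whole = core + satellite holds pre-normalization;
samples with zero stratum total are excluded from that stratum and
logged. The abundance filter keeps pathways holding strictly more than
1 % of the pooled table's grand total (pooled rather than per-group — the
choice that makes the kept set group-independent). Satellite-exclusive
pathways are those positive somewhere in the satellite stratum and zero
everywhere in core.

CLR: zeros are replaced by half the smallest positive value of the whole
table, applied per sample with the positive entries scaled down so the
sample total is preserved (multiplicative replacement); then
clr(x)ᵢ = ln xᵢ − mean(ln x). Per-sample CLR values sum to zero to 10⁻⁹.
The EC→module analysis is the same machinery with a different mapping
file; there is no separate code path.

## Constrained ordination

RDA column-centres the response, regresses it on the (dummy-coded,
centred) design, and takes constrained inertia as the sum of squares of
fitted values, so the explained fraction equals 1 − RSS/TSS of an
ordinary multivariate regression — an identity tested to 10⁻⁸. Species
responses are Hellinger-transformed for RDA; CCA uses raw relative
abundances converted internally to chi-square standardized residuals
(P − rcᵀ)/√(rcᵀ) with row-weighted regression, so total inertia equals
the contingency χ²/N and CCA collapses to plain correspondence analysis
when the design spans the sample space. Categorical covariates are
dummy-coded against a first-level reference and tested as blocks
(df = levels − 1). Rank-deficient designs are fit on the reduced rank via
pivoted QR and flagged.

The pseudo-F test of adding a candidate conditions on the already-selected
block: F = (added inertia/df_added)/(residual inertia/df_residual), with
the null built by permuting the rows of the reduced-model residuals
(Freedman–Lane) — 999 permutations by default and the same +1 P
estimator as ANOSIM. In the CCA space the row weights stay attached to
the residual rows under permutation; this is the standard approximation
and is calibrated in the test suite. Forward selection adds the candidate
with the largest added inertia while its permutation P ≤ α (default
0.05), keeps a full audit trail of every candidate's gain at every step,
and accepts the empty selection as a valid outcome.

## Synthetic cohorts: what they emulate

The generator plants the structure the pipeline is meant to detect, with
defaults chosen once to match the study conditions this package models:
3 groups × 12 samples, 40 core + 160 satellite taxa, core prevalence
0.95, satellite prevalence 0.3, core mean log₁₀ percent abundance 0.0
with SD 0.5 (so core mean abundances are log-normal by construction),
satellites 4× lower in abundance (giving the control group a core
abundance share around 75 %), a 2× satellite expansion in both disease
groups, logistic occupancy–abundance coupling with slope 1.5 per log₁₀
unit (producing the positive distribution–abundance regression), per-
sample log-normal noise (SD 0.3), and exact multinomial sampling at
50,000 reads. An optional Dirichlet overdispersion parameter exists for
robustness experiments but is off by default — the multinomial is the
simplest model that exercises every stage. Pathway incidence is binary:
20 pathways on random taxa community-wide plus 5 assigned only to
satellite taxa, with per-sample contributions equal to taxon counts.

Because relative abundances are closed, a 2× expansion of satellite
*absolute* abundance does **not** double the satellite *share*; the
faithful estimator of the planted multiplier is the satellite:core odds
ratio (s/(1−s) ratios between groups), which inverts the closure exactly
and is what the recovery tests and the acceptance script report (the raw
share ratio is biased toward 1 and would sit near 1.5 under the default
share).

What passing these tests shows: every stage detects, at realistic sizes,
exactly the structure it claims to measure, with calibrated error rates.
What they do not show: robustness to real-data features the generator
omits — taxon-taxon correlations, overdispersion beyond the multinomial,
sequencing batch effects, contamination, variable library sizes, or
taxonomy misassignment.

## Problem sizes and seeds

Null-calibration checks use 500–1000 replicates with 99–199 permutations
per replicate; with the +1 estimator these permutation counts put the
nominal 0.05 level exactly on the attainable P grid, so the calibration
band is a property of the test, not of the grid. Parameter-recovery
checks average 10–20 independent cohorts at the default conditions. All
randomness flows through explicit integer seeds (per-stage seeds are
spawned from one global seed in the pipeline and recorded in the
manifest), and reruns of the pipeline with the same config and seed are
bit-identical.

## Known limitations

- ANOSIM's exact mode enumerates label assignments and is guarded to
  small n (n! ≤ 10⁶).
- The chi-squared log-normal GOF with moment-fitted parameters is mildly
  anti-conservative in theory; the df = bins − 3 correction keeps it
  calibrated at the sizes tested (n ≥ 16).
- CCA forward selection permutes weighted residual rows, an approximation
  exact only under equal row masses; sample depths are equal by design in
  simulated cohorts and near-equal after rarefaction in practice.
- BIOM ingestion is not provided; count tables enter as TSV.
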