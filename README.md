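# coresat

Core/satellite partitioning and downstream community analysis for amplicon
microbiome cohorts.

## The problem

Gut microbiome case-control studies (here modelled on a cohort of one
healthy control group and two disease subtypes) routinely need the same
analysis chain: split the community into the **common core** taxa — those
present in at least a prevalence threshold of a group's samples, here
≥ 75 % — and the rarer, more opportunistic **satellite** taxa, then compare
the partitions across groups by diversity, composition, predicted function
and clinical covariates. `coresat` packages that chain as a tested library
with a synthetic-cohort generator that carries planted ground truth, so
every stage can be validated against known structure instead of
unreproducible raw reads.

## What it computes

- **Partitioning** (`coresat.partition`) — per group, each taxon's
  distribution *d* (% of samples occupied) and mean percent abundance *ā*
  over occupied samples; OLS of log₁₀ *ā* on *d* with
  *F* = (R²/1)/((1−R²)/(n−2)); core iff *d* ≥ 75 %; χ² goodness-of-fit of
  core log₁₀ *ā* to the normal law (equal-probability bins, df = bins − 3).
- **Alpha diversity** (`coresat.diversity`) — Fisher's log-series α solving
  S = α·ln(1 + N/α) on raw counts; Shannon H′ = −Σ pᵢ ln pᵢ on counts
  rarefied without replacement; Kruskal–Wallis and pairwise Mann–Whitney U
  across groups.
- **Community structure** (`coresat.beta`) — Bray–Curtis
  d(j,k) = Σ|xᵢⱼ−xᵢₖ|/Σ(xᵢⱼ+xᵢₖ); intra/inter-group similarity summaries;
  ANOSIM R = (r̄_between − r̄_within)/(n(n−1)/4) with permutation P (exact
  enumeration available for small n) and Bonferroni-adjusted pairwise runs;
  SIMPER additive decomposition of mean between-group dissimilarity; PCoA
  with 95 % confidence ellipses.
- **Predicted function** (`coresat.functions`) — aggregation of KO/EC
  contributions to level-3 pathways, core/satellite stratification,
  satellite-exclusive pathway detection, the > 1 %-abundance filter, CLR
  transform with multiplicative zero replacement, and per-pathway group
  tests (Kruskal–Wallis + Benjamini–Hochberg, pairwise MWU + Bonferroni,
  or ANOVA).
- **Constrained ordination** (`coresat.ordination`) — RDA (Hellinger
  response) and CCA (chi-square residuals, row-weighted) with forward
  selection driven by Monte-Carlo pseudo-F permutation tests.
- **Synthetic cohorts** (`coresat.simulate`) — log-normally distributed
  core abundances, low-prevalence satellites, logistic
  occupancy–abundance coupling, group-specific satellite expansion,
  multinomial sampling at fixed depth, and planted taxon-to-pathway
  incidence with satellite-exclusive pathways.

## Worked example

```sh
python examples/02_partition_core_satellite.py
```

prints (abridged):

```
taxa summarised: 192
distribution-abundance regression: slope=0.0112 R^2=0.39 F(1,190)=120.2 P=5.53e-22
partition at >= 75% prevalence: {'core': 44, 'satellite': 148}
core log-normal GOF: chi2=0.86 df=4 P=0.930
core abundance share (control mean): 67.7 %
```

The positive, highly significant slope is the distribution–abundance
relationship: taxa occupying more samples are also more abundant where
they occur, which is what justifies a prevalence-threshold partition. The
44 core taxa (a quarter of the community) carry about two thirds of all
reads, and their mean abundances are consistent with a log-normal law
(P = 0.93), the expected shape for an established core community. The
other scripts in `examples/` walk the remaining stages (diversity,
ANOSIM/SIMPER/PCoA, pathway profiles, forward-selected ordination) the
same way, and `coresat run-all --config cfg.yaml` (or
`coresat.run_all(PipelineConfig(...))`) chains everything with a hashed,
reproducible run manifest.

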