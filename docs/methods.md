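# Methods

This note documents the models, numerical choices and synthetic-data
design behind `soytol`, and what its tests do and do not demonstrate.

## Physiological panel and change rates

The panel is a tidy table of replicate measurements per (cultivar,
indicator, condition). The change rate of a cell is the relative change of
the condition means, (stress − control) / control. The sign is preserved
because indicator directionality matters downstream; the rate is undefined
when the control mean is zero, which is reported as an error naming the
cell rather than propagated as NaN. Every cell must carry at least two
replicates so the significance tests have within-group variance.

Per-cell control-vs-stress significance uses Welch's unequal-variance
t-test — the robust default at n = 3, where the pooled-variance test's
equal-variance assumption cannot be checked. Degenerate cells follow a
fixed convention: both groups constant and equal ⇒ p = 1; both constant
but different ⇒ p = 0 with a warning. Star labels come from the finest
alpha level beaten (default levels 0.05 / 0.01 / 0.001).

Pairwise correlations of the change rates across cultivars gate the
method per column with a Shapiro–Wilk test at α = 0.05: a pair uses
Pearson only when both columns look normal, otherwise Spearman — the
conservative choice when one variable is clearly non-normal. Significance
defaults to α = 0.01 and is configurable. Constant columns yield
undefined correlations, reported as missing with a warning.

## Ranking model

Standardization is directional min–max: positive indicators map the
column minimum to 0 and maximum to 1, negative indicators (MDA, Pro) are
reversed. A constant column makes the formula 0/0; it is filled with the
neutral membership 0.5 (neither rewarding nor penalizing any cultivar),
flagged, and carries zero entropy weight.

The membership composite is u_i = Σ_j w_j X_ij with w_j = 1/m by default.
Entropy weights use the standard construction p_ij = X_ij / Σ_i X_ij,
e_j = −(1/ln n) Σ_i p_ij ln p_ij (0·ln 0 = 0), w_j ∝ 1 − e_j; an all-zero
column is zero-information (weight 0, warned) and an entirely
zero-information matrix is an error. TOPSIS computes Euclidean distances
to the per-column max/min profiles and the relative closeness
C_i = D⁻/(D⁺ + D⁻); it is **unweighted by default** — the written method
applies the distances to the standardized matrix directly — with entropy
or user weights as opt-in column scalings. Rankings sort by score
descending with a deterministic lexicographic tie-break on cultivar id;
score comparisons use a 1e−9 tolerance for weight sums.

PCA of the column-centered standardized matrix is reported as a
diagnostic only (explained-variance ratios, loadings, scores). The
composite score contains no PCA term, so PCA never alters the ranking.

Concordance between two orderings uses the tie-free closed form
ρ = 1 − 6Σd²/(n(n²−1)) on permutation ranks (ties cannot arise from
positions), Kendall τ on the same ranks, and the number of items whose
positions differ. Because a single item cannot move alone, the reversal
count is never 1. For the nine-cultivar benchmark orderings carried in
`soytol.datasets` (the composite ordering and the TOPSIS ordering differ
by one adjacent exchange) this gives ρ = 0.9833 with 2 reversals; the
package additionally reports score-level Spearman/Pearson between u_i and
C_i, since score-level and rank-level correlations need not agree.

## Differential expression and intersection

The DE stage is a deliberate replicate-based surrogate for count-model
engines (which need read counts): per group, log2fc is the difference of
condition means of log2(FPKM + pseudocount), p comes from a vectorized
Welch test on those log2 values, and FDR from Benjamini–Hochberg across
the group's genes. The call rule is the threshold filter: linear fold
change 2^|log2fc| > 1.5 (read two-sided on the linear scale, so up- and
down-regulation are symmetric; configurable) AND fdr < 0.05, signed by
log2fc. The pseudocount defaults to 1 on the FPKM-like scale to guard
log(0). The shared set is the intersection of differential calls (either
direction) across all groups; all 2^k − 1 Venn region cardinalities are
reported and partition the union of differential genes.

## Co-expression core

Built from scratch on Pearson correlations of log2 expression:

- **Adjacency**: unsigned |cor|^β by default (signed ((1+cor)/2)^β
  available). Self-edges are excluded from all connectivity sums.
- **Soft threshold**: for each candidate β the signed scale-free fit index
  is the R² of the log10 frequency vs log10 mean-connectivity regression
  over ten equal-width connectivity bins, signed positive when frequency
  decays with connectivity; the chosen β is the first to reach the target
  (0.9), falling back to the argmax with a warning when no candidate
  reaches it (typical for simulated data with a handful of planted
  modules, which are not scale-free).
- **TOM**: t_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij),
  t_ii = 1; a zero denominator (isolated pair with a_ij = 1) takes the
  limit value 1.
- **Module detection**: average-linkage clustering of 1 − TOM with a
  static cut at 0.99 × the maximum merge height, replacing the dynamic
  tree cut algorithm (a separate method in its own right) while honoring
  the stated parameters exactly: minimum module size 30 (smaller clusters
  join module 0, the unassigned pool) and iterative merging of module
  pairs whose eigengene correlation exceeds 1 − 0.25. Modules are
  relabeled 1..K by decreasing size. Module 0 is never merged and never
  trait-linked.
- **Eigengenes**: first principal component of the per-gene z-scored
  module expression, scaled to unit variance and oriented to correlate
  positively with the module's mean standardized profile. The orientation
  makes the eigengene deterministic (immune to the SVD sign ambiguity)
  and stable under sign flips of a minority of member genes; flipping an
  entire module necessarily flips its eigengene, as it must under any
  equivariant rule.
- **Module–trait correlation**: Pearson r and p per (eigengene, trait);
  the trait-linked module per trait maximizes |r|.
- **Hubs and candidates**: intramodular connectivity k_within(g) is the
  sum of g's adjacency to its module co-members (adjacency-based by
  default; TOM-based via a flag, since either convention is found in
  practice); each module's hubs are the top 30 by k_within with a
  lexicographic tie-break. Candidate genes are hubs of trait-linked
  modules intersected with the shared differential set, sorted by gene
  id with (module, k_within) provenance.

The "expression threshold 2" is read as a minimum-max-abundance filter:
a gene is kept when its maximum abundance across samples is ≥ 2 (FPKM
equivalents, inclusive); a variance- or fold-based reading is possible
and the threshold is exposed in configuration.

## Synthetic data

`gen_physio_panel` plants an evenly spaced latent tolerance gradient
t ∈ [0, 1] over cultivars. Control replicates are baseline × (1 + ε),
stress replicates baseline × (1 + slope·g(t) + ε) with ε ~ N(0, noise_sd),
g(t) = t for positive indicators and 1 − t for negative ones — so MDA- and
Pro-like indicators respond more strongly in sensitive cultivars and
their change rates decrease with tolerance. Defaults mirror a 9-cultivar
× 7-indicator × 3-replicate design with slopes sized so change rates span
roughly 0–80%. At zero noise the ranking by any single indicator equals
the gradient exactly; the Gaussian relative-error model is a stand-in,
not a claim about any real panel's error distribution.

`gen_expression_study` builds a log2-scale latent matrix and returns
2^latent as FPKM-like abundances:

- **Module factors** take one value per (cultivar, tissue) unit, shared
  by both conditions — so module membership alone never creates
  differential expression — plus small replicate noise (rep_sd = 0.05),
  standardized across samples. The unit-level values of the different
  modules are centered and orthogonalized (QR), making planted modules
  mutually uncorrelated; with U units at most U − 1 such factors exist
  (the default four-group design supports the default three modules).
- **Module genes** are mu + b·F + noise with b chosen so the expected
  pairwise member correlation equals `within_corr` (default 0.8); planted
  hubs use `hub_within_corr` (default 0.995), making them tight factor
  followers with top intramodular connectivity. Module-gene baselines are
  raised by 2b so abundances stay well above the DE pseudocount over the
  factor's swing, keeping planted log2 fold changes interpretable.
- **DEGs** are centered additive log2 contrasts (±log2fc_effect/2 on
  stress/control samples of the affected group, default effect 2) with an
  independent random sign per group, so shared genes are differential in
  every group without forming a correlated block of their own. Per-group
  up/down sets are filled to the requested counts (default 80/80) with
  group-exclusive genes; the shared set (default 39) draws
  `shared_hub_count` genes (default 13) from planted module hubs —
  these are the planted candidate genes — and the rest from unassigned
  genes.
- **Traits**: each linked trait is its module's factor times the link
  sign plus N(0, 0.2) noise; unlinked indicators are pure noise.

All draws come from sub-streams of one SeedSequence (fixed spawn keys;
per-cultivar and per-gene streams), so outputs are byte-reproducible and
adding genes does not perturb earlier genes' draws.

What passing tests show — and do not. The generator emulates the
*structure* of a two-condition multi-tissue study: planted gradients,
condition-balanced co-expression modules, additive DE on the log scale,
linear trait links. It does not model count overdispersion, library-size
effects, batch structure, correlated indicator errors, or module overlap,
so recovery results bound what the pipeline can do under its own
assumptions, not its accuracy on any real dataset (whose printed DEG and
module counts are likewise out of reach without the raw data).

## Problem sizes and defaults of the demonstration study

The packaged demonstration configuration (`soytol.pipeline.demo_config`)
simulates 9 cultivars at physiological noise 0.02 and an expression study
of 1000 genes with the default three modules (60/50/40), 39 shared DEGs
and 13 hub-resident candidates, over the four cultivar × tissue groups
with **5 replicates per condition**. Five rather than three replicates is
a deliberate choice for the exact-recovery demonstration: with
triplicates the Welch test has ≈2 degrees of freedom, which floors
attainable p-values near the BH threshold and makes exact recovery of a
39-gene set a matter of luck rather than signal. The generator's own
default stays at 3 replicates, mirroring the common assay design.

Other fixed sizes: ranking recovery uses 9×7 panels at noise 0.02 over 20
seeds (Kendall τ ≥ 0.9 against the planted order); module recovery uses
200 genes (three planted modules of 60/50/40 at within-correlation 0.85,
noise 0.3, 24 samples, 50 unassigned genes) over 10 seeds with the
package's own soft-threshold selection, scored by adjusted Rand index
≥ 0.8; oracle checks enumerate all 2×2 decision matrices on the five-step
unit grid and all 3×2 matrices on a three-step grid plus 1500 seeded
random 5×4 grid matrices (full enumeration of 5×4 grids is combinatorially
impossible), and 100 random 20-gene adjacencies, at 1e−12 agreement.

## Known limitations

- The static cut is coarser than dynamic tree cutting: near the cut
  height, weakly attached genes can join a module (inflating it) or split
  off; the eigengene-merge step recovers over-split modules but not
  over-merged noise.
- Group-specific DEG blocks share a condition contrast and legitimately
  appear as modules of their own under unsigned adjacency; they are
  condition driven, correlate with no physiological trait, and therefore
  never enter the candidate intersection.
- With four sample units only three mutually orthogonal condition-balanced
  module factors exist; configurations with more planted modules than
  units − 1 will show chance inter-module correlation (warned).
- The Welch surrogate DE test is not a count model; its calls agree with
  the threshold rule on the log2 scale but are not calibrated against any
  specific DE engine.
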