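# Methods

`epiaging` implements an end-to-end analysis of accelerated epigenetic
aging in neurodegenerative disease (ND) cohorts — Alzheimer's (AD),
Parkinson's (PD), progressive supranuclear palsy (PSP) and frontotemporal
dementia (FTD) — from DNA-methylation profiles. Because the analysis is
developed and validated without access to clinical cohorts, a synthetic
generator reproduces the statistical structure the method assumes, with
ground truth recorded so every stage can be scored on recovery of planted
signal.

## Data model and pre-processing

The working object is a samples × CpG-sites matrix on a continuous
normalized (M-value-like) scale with per-sample age, group label
(`young`, `control`, `AD`, `PD`, `PSP`, `FTD`) and train/test split.
Site values are generated on a Gaussian scale rather than the bounded
beta scale: every downstream computation (z-scores, Pearson and partial
correlations, tree splits) is scale-agnostic, and an unbounded scale
avoids boundary artifacts when planting correlation structure.

Pre-processing runs in a fixed order:

1. sites with ≥ 30% missing entries are deleted (strict: a site exactly
   at the threshold is removed);
2. remaining gaps are imputed by the unweighted mean of the k = 10
   nearest samples, with Euclidean distance over mutually observed sites
   rescaled by the shared-site count (optionally within a stratum such as
   a brain-region annotation; strata smaller than k + 1 fall back to all
   available neighbors with a logged warning);
3. samples without an age are dropped;
4. disease samples with age ≤ 50 (early onset) are dropped — young
   controls at the same ages are kept;
5. every site is z-scored against the healthy aged (control) samples'
   mean and SD; zero-variance reference sites are dropped;
6. the top 3 right-singular directions of the centered control submatrix
   are removed from every sample (SVD batch correction);
7. a second z-score pass against the same reference restores unit
   reference scale, and a 2:1 train/test split is drawn stratified by
   group (groups with < 2 samples go wholly to train).

Both z-score passes use the healthy *aged* reference; the alternative
(all healthy individuals in pass 5) is a plausible reading of the
protocol but the aged-only choice keeps the young group's departure from
the reference interpretable as an aging axis.

## Marker selection

Sites are ranked by ReliefF (all instances, 10 near-hits/near-misses,
unit-range feature scaling; implemented in-package since no installed
library provides it). The classifier is discrete AdaBoost over depth-2
decision trees: with sample weights D_n (D_1 = 1/m) and weighted error
ε_n, the round weight is α_n = ½ ln((1 − ε_n)/ε_n); misclassified samples
are multiplied by √((1−ε_n)/ε_n), correct ones by its inverse, and
weights are renormalized. A round with ε_n = 0 ends boosting with that
learner; ε_n ≥ 0.5 resets the weight state and retries with a fresh tree
seed (bounded retries). The default ensemble size is 100 rounds. The
per-sample multiplicative update is the standard scheme consistent with
the ½·ln round weight; a global weight recursion is not a usable
alternative reading.

Marker sets come from sweeping the top-k ranking prefix, k = 1..50,
under stratified 10-fold cross-validation of the boosted classifier and
taking the k with the highest mean CV accuracy, ties resolved toward the
smallest k (parsimony). Disease predictors balance the class masses by
partitioning the aged controls into 3/9/7/3 random subgroups (AD, PD,
PSP, FTD); each subgroup is paired with the full disease sample,
per-pairing ReliefF rankings are combined by rank-sum, the selected
dimension is the rounded mean of per-pairing CV choices, and the final
model is refit on all controls plus disease samples with per-sample
weights equalizing the two class masses. The aggregation rule (rank-sum
plus weighted refit) is this package's construction; only the
subgrouping itself is prescribed.

## Aging and disease scores

The aging score is the output of 100 bootstrap-aggregated regression
trees trained on the selected aging markers with young = 0, aged = 1.
Trees are depth-limited (default depth 2): fully grown trees memorize
the 0/1 codes and saturate the score at the class extremes, which
collapses the within-aged gradient that the age-stratified comparisons
measure; shallow trees keep the score graded across the aged range. The
prediction is the unclipped mean of tree outputs. Disease risk scores
reuse the same regressor with control = 0 / disease = 1 over the disease
markers.

Chronological age enters through the sigmoid transform
`t(age) = 1/(1 + exp(−(age−50)/50))` (0.5 at age 50, limits 0 and 1);
the adjusted score is `b·score − t(age)` where `b` is the slope of the
with-intercept OLS regression of t(age) on the score — only the slope
enters, per the score definition. Score normality is tested with a
one-sample Kolmogorov–Smirnov statistic against a normal law with the
sample moments. Aging acceleration is tested by Kruskal–Wallis
(midranks, tie correction) between ND and control scores restricted to
age ≥ t for t ∈ {50, 55, …, 80}; strata missing an arm are skipped.
Downstream network conditioning uses the raw aging score; the adjusted
score is reported alongside.

## Aging-acceleration differential network

For every candidate pair of sites, Pearson r (p from the t-transform,
n−2 df) and the first-order partial correlation given the aging score
(`(r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))`, n−3 df) are computed
separately in the control-aged group and the disease group. p-values are
Benjamini–Hochberg adjusted per statistic family (four families across
all candidate pairs). Each group contributes one difference value
δ_g = r_g − pr_g — how much conditioning on the aging axis reshapes the
pair. An edge is retained iff sign(δ_ND) ≠ sign(δ_ctrl) and the minimum
of the four adjusted p-values is < 0.1. Both ambiguous readings are
exposed: the between-group variant (sign of Δr vs sign of Δpr) and an
"all four q-values" gate are config switches; defaults are as stated.
The candidate universe is the union of aging and disease markers plus
the top-variance sites (default 500), since an all-pairs universe over
~23k sites is outside desk scale.

The synthetic fixture for this stage plants pairs whose correlation is
+ρ in control-aged samples and −ρ in disease samples via a Gaussian
copula; one member of each pair additionally loads on the
standardized-age latent with the maximal feasible loading √(1−ρ²). This
coupling is what makes the flip visible to the marginal-vs-partial rule:
conditioning on the aging score shrinks or inflates the pair correlation
through the shared aging axis, so δ carries the sign of the group's
correlation, and the sign flip produces opposite-signed δ's. A pure
sign-flip pair with no aging coupling changes its marginal correlation
but leaves δ ≈ 0 in both groups, which no δ-based rule can see.

Network checks: degree distributions are tested for a power-law shape by
least squares on log10 P(d) vs log10 d (≥ 3 distinct degrees required,
≥ 10 preferred); train/test network concordance uses a one-sided Fisher
exact test on the 2×2 edge-overlap table over the candidate universe.
Shortest aging→disease paths use unit edge weights (no weights are
defined), making Dijkstra BFS-equivalent; among equal-length paths the
lexicographically smallest node sequence is returned for determinism.
Path-restricted betweenness counts interior appearances of a node on the
aging→ND path set; its permutation p redraws the source/target labels
uniformly among network nodes and uses the add-one convention
p = (1 + #{perm ≥ obs})/(n_perm + 1), so the smallest attainable p is
1/(n_perm+1) and never 0.

## MCMC global sensitivity

A random-walk Metropolis–Hastings chain (symmetric Gaussian proposals,
so the Hastings ratio cancels) samples marker-space profiles over the
union of aging and disease marker sites. The sampled law is the
independent-normal distribution with per-site means/SDs estimated from
the normalized aged-control data: no likelihood is defined for this
stage, so the scan is prior-predictive — it probes the fitted scorers
over the plausible range of marker profiles rather than a posterior.
This is the central modeling decision of the stage and the main caveat
when interpreting its output.

Defaults: 20,000 draws, 5,000 burn-in, proposal SD =
min(0.5, 2.38/√d) × prior SD per coordinate (the classical random-walk
scaling; a fixed 0.5 collapses acceptance once the marker union reaches
tens of coordinates), with an acceptance-rate sanity band of [0.1, 0.7]
logged.
For each draw the aging score and each disease risk score are computed;
a marker's sensitivity is the two-sample K–S sup-distance between the
output CDFs of draws with negative vs non-negative chain-normalized
marker value (coordinates whose draws are one-sided are flagged
undefined). The differential for marker x in disease d is
KS_aging(x) − KS_d(x); an "aging–ND pair" (a, m) is scored
|diff(a,d)| + |diff(m,d)| (the pair-level statistic is not otherwise
defined), ranked descending with lexicographic tie-breaks, and each
aging marker's frequency across the diseases' top-n lists highlights
markers shared by multiple diseases. A pooled-output variant (mean of
aging and all disease scores) probes common characteristics.

## Enrichment

Genes of the CpG sites on each disease's shortest paths (union,
deduplicated, unannotated nodes dropped) are tested against GMT gene
sets with the hypergeometric upper tail
P(X ≥ k) = Σ_{j ≥ k} C(M,j)C(N−M,n−j)/C(N,n), evaluated in log space
with gammaln binomials; the printed normalizer in the source formula is
read as C(N,n), the only consistent denominator. The background N is all
annotated genes (configurable). p-values are BH-adjusted per collection
and called at FDR < 0.05. The BH routine is one shared implementation
used by both the network and enrichment stages.

## Synthetic generator: what it does and does not emulate

Planted structure: aging markers gain `aging_effect` SD per decade of
(age − 50) — default 0.5; disease markers gain a mean shift in their
disease only; disease samples carry the aging slope at 1.5× (the
accelerated-aging pattern is asserted by the analysis only
qualitatively, so the multiplier is a study condition, not an estimate);
per-cohort per-site offsets emulate batch structure; entries go missing
completely at random; ages are integers, uniform on [20, 50] (young) and
[51, 90] (aged/disease), with the young/old boundary fixed at 50.

Not emulated: array chemistry, probe cross-hybridization,
platform-specific normalization across the seven array platforms of the
original series, beta-scale boundary effects, spatial correlation along
the genome, and realistic linkage between CpG islands and genes (the
annotation is a random surjection). Passing recovery tests therefore
demonstrates that the pipeline detects the structure it is designed for
at realistic effect sizes and sample sizes — not that real cohorts meet
those assumptions.

## Problem sizes used by the validation experiments

The validation experiments (tests and `scripts/acceptance.py`) run at
desk scale, chosen once as the package's own sizing:

- null calibration: 20 reseeds, 75 samples/class, 100 sites, selection
  sweep k ≤ 10, 3 folds, 20 boosting rounds;
- marker recovery: 10 reseeds, 20 planted markers at 0.5 SD/decade among
  500 sites, 100 samples/class, k ≤ 50, 10 folds, 20 boosting rounds;
- accelerated aging: 20 reseeds with about 440 aged controls vs 330
  pooled ND samples (cohort sizes typical of pooled multi-center brain
  methylation studies), 100 score trees;
- sign-flip recovery: 10 pairs at ρ = 0.8, 150 samples/group, 80 sites;
- MCMC: 20k draws for moment recovery; 4k draws per reseed for the
  planted-driver scan over 20 sites.

Library defaults remain the standard constants (100 trees, 10 folds, k ≤ 50, FDR 0.1/0.05, KNN k = 10, SVD 3 components, 2:1
split).

## Known limitations

- The prior-predictive reading of the sensitivity stage means its
  rankings describe the fitted scorers, not a data posterior.
- The CV-parsimony rule (smallest k on ties) can truncate the selected
  marker set when few markers already saturate CV accuracy; recovery of
  a planted marker set is correspondingly conservative.
- The permutation scheme for betweenness p-values (marker-label redraw)
  is one of several defensible nulls.
- Balanced disease fitting aggregates subgroup rankings by rank-sum;
  other aggregations (e.g. score averaging) are plausible.
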