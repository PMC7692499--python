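# Methods

`gliotype` implements a transcriptome-based tumor-subtyping workflow in two
halves: an unsupervised discovery step (density-based UMAP consensus
clustering, "DBU") and a supervised, portable classifier (an ensemble of
linear support-vector classifiers combined by confidence-scored plurality
voting, "ETC"), followed by the standard downstream characterizations —
mutation enrichment, survival stratification, tumor-purity comparison and
concordance with other classification systems. Everything is exercised
end-to-end on simulated cohorts with known ground truth.

## DBU: density-based UMAP consensus clustering

One DBU iteration subsamples `genes_per_iteration` genes from a standardized
gene × sample matrix, embeds the samples in 2-D with UMAP
(`n_neighbors=5`, `min_dist=0`, manhattan metric on the input space), and
clusters the embedding with DBSCAN (Euclidean in the embedding). DBSCAN
noise is recorded as the reserved label 0. Repeating this many times over
random gene subsets turns the stochasticity of the embedding into a vote:

1. **Filtering.** Iterations whose cluster count differs from the expected
   count (the modal count when `expected_groups="auto"`) are discarded.
2. **Alignment.** Cluster ids are arbitrary per iteration. A reference
   iteration is chosen as the retained iteration with maximal mean pairwise
   agreement (adjusted Rand index), its clusters renumbered by order of
   first appearance, and every other iteration's labels permuted to
   maximize sample overlap with it (optimal assignment on the contingency
   matrix; the noise label is never remapped). Among tied-optimal
   permutations the one giving the lexicographically smallest aligned label
   vector is used, which makes the whole consensus invariant to how each
   iteration happened to number its clusters.
3. **Consensus.** Each sample's votes are tallied over the retained,
   aligned iterations. A sample is assigned to its top non-noise cluster
   only if that cluster holds at least the ambiguity threshold (default
   70%; exactly 70% passes) of the votes *and* noise is not the single most
   common label; otherwise the sample is "ambiguous".

### eps selection

DBSCAN's `eps` can be given numerically (the full-cohort-scale default is 1.55) or
derived per embedding from the knee of the sorted k-th-nearest-neighbor
distance curve with k = `min_points`: both axes are rescaled to [0, 1], the
curve lightly smoothed (window ≈ n/20), and the point of maximum discrete
curvature taken. Normalizing the axes makes the knee scale-free; without it
the curvature maximum chases the extreme tail of the curve.

### Subcluster probing

A consensus group can hide substructure that most iterations do not resolve
(in particular a low-purity subpopulation diluted toward normal tissue).
`subcluster_group` re-runs DBU on the group's samples with density
parameters rescaled to the subset: `min_points` shrinks proportionally to
the subset size, and the UMAP neighborhood is floored at ~10% of the subset
(a 5-neighbor graph on ~150 samples fragments even a homogeneous cluster
into clumps). Because genuine substructure typically appears in only a
minority of subset iterations, the split decision is not the modal cluster
count: the iterations that report ≥ 2 clusters are aligned and voted among
themselves, and the split is accepted only when that consensus is coherent —
at most half the subset ambiguous and at least two subgroups each no smaller
than the rescaled `min_points`. On homogeneous groups the multi-cluster
iterations are mutually inconsistent, the consensus collapses, and the group
is left intact. Accepted subgroups are labeled `<group>a`, `<group>b`, … by
decreasing size.

## ETC: ensemble transcriptomic classification

**Signature.** Candidate genes are ranked by their best BH-adjusted
one-vs-rest p-value (vectorized Welch t per group versus rest — a moderated
linear-model test would serve the same ranking purpose; only the ranking is
consumed). Recursive feature elimination under a linear SVC (squared hinge,
C = 1, one-vs-rest; genes ranked by the sum of squared class weights,
removing `step=5` genes per round) reduces the candidate pool to an exact
target size. A curated gene list supplied by the analyst joins afterwards,
exempt from pruning. Signature genes are then partitioned into six
expression-pattern groups by k-means (50 restarts, fixed seed) on their
z-scored per-subtype mean profiles, so only the *pattern* across subtypes
matters, not the expression level.

**Dictionary.** Each ensemble member draws half of every expression-pattern
group (rounded down) at random and runs RFE on the union, this time keeping
the smallest gene set attaining the maximum threefold cross-validated
accuracy (ties go to fewer genes). Entries whose CV accuracy falls below
the floor (default 95%) are dropped.

**Cross-fitting and voting.** In-cohort calls are leak-free: labeled samples
are split into four stratified folds, each entry's classifier is trained on
three folds and votes only on the held-out fold, so no sample is classified
by a model that saw it. Samples the unsupervised step called ambiguous are
never trained on and are voted on by entries fitted to the full labeled
cohort. Votes are hard class predictions; with p1 and p2 the vote shares of
the two most popular classes, the confidence score is p1/p2 (∞ when p2 = 0)
and the call is the top class only when the score exceeds 3 — a score of
exactly 3, and any exact top tie (score 1), is "ambiguous".

**Cross-platform prediction.** An external cohort is standardized within
itself and may lack signature genes (an error is raised below 50%
coverage). Entries missing genes are refit on the training cohort
restricted to their surviving genes — refitting preserves each entry's
decision geometry on the available features, whereas zero-imputing
standardized inputs would bias the linear scores — and entries left with
fewer than two genes abstain; the vote denominator is the number of entries
actually voting.

## Characterization

- **Mutation enrichment**: per gene and group, a one-vs-rest 2×2 Pearson
  chi-squared without continuity correction (tables with a zero margin are
  reported as null; expected counts < 5 are flagged), BH-adjusted across
  all gene × group tests. Genes mutated in no sample are removed first.
- **Survival**: Kaplan–Meier product-limit curves with censor marks, the
  k-sample log-rank test, and univariate Cox hazard ratios (Efron ties, via
  lifelines) versus a reference group with 95% CIs. Median survival is
  "not reached" (NaN) when the curve never crosses 0.5; groups with no
  events get a non-estimable HR with a warning.
- **Purity**: median [IQR] per group (ambiguous samples form their own
  group) plus one-way ANOVA across groups with ≥ 2 members.
- **Concordance**: cross-tabulation of two labelings with agreement
  computed under an optimal one-to-one class matching, making the statistic
  symmetric and invariant to label renaming; a user-supplied semantic
  mapping overrides the automatic matching. Ambiguous samples are excluded
  by default or kept as a category by flag.

## The synthetic cohort generator

The generator produces the structure the pipeline must resolve, with full
ground truth. Expression for sample *i* of subtype *k* with tumor purity
*p<sub>i</sub>* is

    x_i = p_i · (mu_k + eps) + (1 − p_i) · (nu + eps'),

followed by per-gene standardization (sample sd). `mu_k` is nonzero on the
subtype's block of informative genes; `nu` is a fixed "normal tissue"
profile drawn once per cohort with per-gene sd 3 (normal brain differs from
tumor across essentially the whole transcriptome, and this global contrast
is what makes dilution visible); noise is unit Gaussian. One subtype (by
default the last, 15% prevalent) duplicates another subtype's tumor profile
and differs only through its purity distribution — Beta with mean 0.60
versus 0.77 elsewhere (concentration a+b = 100, within-subtype sd ≈ 0.04),
mimicking a neuron-rich, low-tumor-content group. Prevalences
(0.40, 0.25, 0.20, 0.15) are unequal by design; the diluted group is kept at
15% so that it remains above density-clustering thresholds at n = 400.

**Effect-size calibration.** `effect_size` is a standardized mean difference
(Cohen's d: subtype versus rest, pooled within-subtype sd) measured on the
generated matrix. A subtype-vs-rest shift expressed in *total*-sd units
saturates mathematically once between-group variance enters the
denominator (the cap is ≈ 2.04 at 40% prevalence), so the within-sd
definition — the standard one for effect sizes — is used instead; it is
unbounded and nearly linear in the raw profile shift. The generator solves
for the raw shift in closed form from two probe evaluations (1/d² is linear
in 1/s²) plus one multiplicative refinement, reusing the same noise draws so
the cohort stays a deterministic function of the seed. For the twinned
subtype the diluted copy is excluded from the reference group, since it
expresses the same program. Realized d lands within a few percent of the
target.

Mutations live in a separate gene namespace (a distinct data modality):
Bernoulli with baseline rate 0.10, multiplied to odds 8 in each subtype's
designated genes, plus unenriched background genes. Survival is exponential
with per-subtype log-hazards (defaults 2.4/0/0.35/0, spanning an aggressive
and an indolent group around a baseline hazard of 0.0087 events/month ≈ an
80-month median) and independent uniform administrative censoring whose
horizon is solved numerically to hit the configured censoring fraction
(default 30%).

`degrade_to_platform` emulates re-measuring a cohort on another expression
platform: a random gene subset is retained (default 161/168 ≈ 96%), each
surviving gene passes through a strictly monotone per-gene transform
(log-normal gain, offset, mild tanh nonlinearity) plus noise, and the result
is re-standardized within itself.

**What the generator does not emulate**: count noise and library-size
effects of RNA-seq, batch structure, correlated gene modules beyond the
subtype blocks, copy-number or methylation signals, or informative
censoring. Passing tests therefore demonstrate that the algorithms recover
the structure they are designed for under realistic noise and dilution —
not that any particular real cohort will be recovered equally well.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the pipeline at a reduced
scale chosen as the smallest that still exercises every mechanism: a
400-sample / 2000-gene reference cohort with DBU at 100 iterations × 500
genes and `min_points` 25, a 200-entry dictionary, fourfold cross-fitting;
the purity–ambiguity analysis pools 20 cohorts of 250 samples (DBU 15 × 300,
`min_points` 15); survival recovery fits 100 cohorts of 2000 samples.
UMAP runs with a fixed `random_state` (single-threaded, fully
deterministic); per-iteration seeds are spawned from the master seed with
`numpy.random.SeedSequence`, so iterations are independent and
order-insensitive. Linear SVCs use `max_iter=5000`; stratified CV folds use
fixed seeds. Zero-variance genes standardize to all-zero rows (kept, so
gene indices stay aligned with signature lists); re-standardizing a
standardized matrix raises rather than silently double-scaling.

## Known limitations

- The subcluster split-acceptance rule is a principled stand-in for a
  procedure that, on real data, involved judgment; its thresholds (half the
  subset non-ambiguous, subgroups ≥ rescaled `min_points`) are sensible but
  not canonical.
- The reference-iteration search is O(m²) in retained iterations; at 1000
  iterations on ~1000 samples it costs tens of seconds.
- The one-vs-rest differential-expression test is a plain Welch t, not an
  empirical-Bayes moderated test; with hundreds of samples per group the
  ranking difference is negligible, but on small cohorts a moderated test
  would rank low-variance genes differently.
- Cross-platform prediction assumes gene identifiers are already harmonized
  between cohorts; identifier mapping is out of scope.
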