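# Methods

## The interaction-strength statistic

The core quantity is a per-sample, rank-based interaction strength for a
gene pair. Within each sample of a bulk cohort, all retained genes are
ranked in descending order of expression; position `pos` (1 = highest,
fractional average positions for ties) is mapped to a normalized rank score

    r = 10 · (G − pos + 1) / G,   r ∈ (0, 10],

for G retained genes, so the most expressed gene scores 10 and the least
10/G. For a pair with scores r₁ and r₂ the per-sample strength is

    IS = (r₁ + r₂) · (10 − |r₁ − r₂|)  ∈ [0, 200].

The first factor rewards joint high expression, the second penalizes rank
divergence; IS = 200 exactly when r₁ = r₂ = 10. Because the statistic uses
only within-sample ranks, it is invariant to any monotone per-sample
transform — scoring raw FPKM or log2(FPKM + 0.05) gives identical results
(asserted by a test). The 0–10 scale is a modeling choice the formula
forces: with ranks on any other scale the `10 − |r₁ − r₂|` term could go
negative or dominate; the continuous scaling (rather than integer deciles)
keeps the map expression → score strictly monotone and tie-consistent.

**Aggregation and significance.** The cohort-level strength is the
arithmetic mean of IS over samples. The null distribution is built from
random ordered gene pairs drawn uniformly (two distinct genes per draw,
the observed pair excluded) from the retained gene universe and aggregated
identically; sample labels are never permuted, since each sample's rank
structure is what the statistic measures. The p-value is the upper tail

    p = (1 + #{null mean IS ≥ observed mean IS}) / (n_perm + 1),

with an add-one correction so p ∈ (0, 1]; the lower tail is available via
`alternative="less"`. A strong pair should be *larger* than random, hence
the upper tail is the default. The null generator for the k-th pair of a
run is seeded with `[seed, k]`, making every p-value reproducible and
independent of how many other pairs were scored in the same call. Under
this scheme the p-values of null pairs are uniform to within binomial
error; the calibration test checks the fraction below 0.05 of 1,000 null
pairs (200 permutations each) against the 99% binomial envelope.

**Preprocessing.** FPKM input; genes with zero expression in strictly more
than 30% of samples are excluded (a gene at exactly 30% is retained);
log2(FPKM + 0.05) is the stored/reported normalization. Cohorts need at
least 6 samples (`min_samples`); prediction tables from single-cell data
are admitted at ≥ 500 cells (`min_cells`), a threshold carried in the run
configuration for callers that filter datasets. Degenerate inputs error
out early: single-gene matrices (ranking undefined), matrices emptied by
the filter, missing values, rank scores outside (0, 10].

## Catalog integration

Pairs are ordered (ligand, receptor) — roles are not interchangeable — and
keyed by Ensembl gene ID when a symbol→Ensembl table is supplied; unmapped
genes keep their symbol and carry a provenance flag rather than being
dropped. Merging is a set union per species: sources accumulate, and the
evidence subclass is `manually_curated` if any contributing source flags
the pair curated. When a source table has no evidence column, a per-source
default declares the whole source curated or predicted, since identification
method is a property of the source. Merge is idempotent, commutative and
associative on the pair set (property-tested).

Functional classification assigns a pair to a group only when both genes
are annotated to it; with several matches, the primary group is the first
in a configurable priority order defaulting to the canonical listing
(notch signaling → cytokine), and all matches are retained in
`all_groups`. A pair with no shared group is `other`. Multi-subunit
receptor complexes are flattened to gene pairs, with complex membership
noted in a free-text field.

Cross-source comparison uses UpSet semantics: for every non-empty subset
of sources, the count of pairs present in *exactly* that subset. These
exclusive counts partition the merged catalog (checked against brute-force
enumeration over all 127 subsets of 7 random catalogs).

## Consensus integration and evaluation

Method-native communication scores are incomparable across algorithms, so
each record first receives a within-method percentile rank (average-rank /
n, in (0, 1]). Consensus = communications predicted by at least
`min_support` (default 2) methods, ranked by the mean of the supporting
percentiles; the output order is deterministic (support desc, consensus
rank desc, key lexicographic, with per-key method order fixed before the
floating-point mean so integration is invariant to input order).
Support-count integration was chosen as the simplest defensible rank
aggregation; the evaluation metrics below do not depend on it and any
other aggregation can be plugged in upstream.

Evaluation uses the classic weighted Kolmogorov–Smirnov running sum: down
a method's score-ranked list, hits add `|score|^exponent` normalized over
in-set scores (exponent 1 by default; 0 gives the unweighted statistic,
invariant to positive affine score rescaling) and misses subtract
`1/(N − N_hit)`; ES is the extremum, |ES| ≤ 1, and ES = 1 when the set is
the whole list. Significance permutes *set membership* (random same-size
key sets), not phenotypes — there are no sample labels here — one-sided on
the observed sign with the add-one correction. In-set weights are rescaled
by their maximum before normalization to avoid overflow on near-zero
scores; a set whose scores are all numerically zero falls back to
unweighted hits. Ties in ranked lists are broken by a stable sort with the
lexicographic key last, so results are reproducible. Top-fraction
occupancy is |set ∩ top-k| / |set ∩ list| with k = ceil(fraction · N).

## Synthetic data

The generators produce the statistical structure the methods assume, not
realistic transcriptomes:

* **Expression** — log-normal FPKM background (meanlog 1, sdlog 1, a
  standard abundance stand-in), optional per-entry zero inflation to
  exercise the 30% filter, and planted pairs whose two genes are raised
  just above a configurable expression quantile (default 0.9) in a
  configurable fraction of samples (default 0.8), tied with each other so
  the pair's rank gap is zero. Planting forces quantiles rather than
  adding shifts because only ranks matter to the statistic. A pair planted
  at quantile 1.0 in every sample reaches the tied-pair maximum
  200·(G − 0.5)/G, not 200 exactly: two tied top genes share average
  position 1.5.
* **LR catalogs** — an overlap design mapping each source subset to an
  exclusive pair count is realized exactly, so intersection statistics are
  known by construction.
* **Predictions** — a shared core scored from a high normal
  (loc 0.75, sd 0.12) plus per-method noise from a lower one (loc 0.30),
  overlapping enough that rankings are nontrivial. Five methods, 50 shared
  and 100 noise predictions per method by default — a desk-scale stand-in
  for multi-algorithm output on one dataset.

Everything is driven by `numpy.random.default_rng(seed)`; identical spec
and seed give byte-identical CSVs. Because the fixtures lack library-size
effects, dropout, batch structure and cell-type mixtures, passing tests
demonstrate algorithmic correctness and calibration, not performance on
real cohorts.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen so each check is
statistically meaningful yet completes in seconds: calibration uses 1,000
null pairs on a 200 × 20 matrix with 200 permutations; recovery uses 20
planted pairs against 200 background pairs; catalog accounting uses 7
random 50-pair catalogs over a 100-pair universe (all 127 subsets);
consensus evaluation uses 5 mock methods. Production runs would use 1000
permutations (the default) and whole-transcriptome matrices; the code is
vectorized over permutations and samples, so cost grows linearly in
pairs × permutations × samples.

Known limitations: no orthology mapping between human and mouse catalogs;
receptor complexes are flattened; the consensus is a rank aggregation, not
a probabilistic model of method agreement; normalized enrichment scores
across set sizes are out of scope (single-set use case); and bulk scoring
cannot attribute a pair to specific sender/receiver cell types without
external deconvolution.
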