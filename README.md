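# lrcomm

Toolkit for studying tumor–immune cell communication through ligand–receptor
(LR) signaling. It is aimed at computational biologists who (a) need one
harmonized LR-pair catalog out of several public resources, (b) want to score
candidate gene-pair interactions on **bulk** RNA-seq cohorts, where standard
single-cell communication tools do not apply, and (c) integrate and
benchmark the predictions of multiple single-cell cell–cell communication
algorithms (iTALK, CellTalker, ICELLNET, NicheNet, …) against each other.

## What it computes

**Catalog integration.** Per-source LR tables (CSV/TSV, configurable column
mapping) are deduplicated, merged per species with provenance tracking, and
labeled `manually_curated` when at least one source has experimental or
manual support, else `predicted`. Pairs are classified into ten
immune-signaling functional groups (notch signaling, antigen binding,
neuropeptide, hormone, growth factor, interferon, interleukin, tumor
necrosis factor, chemokine, cytokine) by requiring *both* genes to carry a
group's GO-derived annotation; unmatched pairs fall into `other`.
UpSet-style exclusive intersection counts across sources are provided.

**Interaction strength on bulk data.** After removing genes with zeros in
more than 30% of samples, every sample's genes get a normalized rank score
r ∈ (0, 10] (10 = most expressed, average positions for ties). For a gene
pair with per-sample scores r₁, r₂,

```
IS = (r₁ + r₂) · (10 − |r₁ − r₂|)
```

which is 200 when both genes top the sample and near 0 when either is
lowly expressed or the two diverge. The cohort-level strength is the mean
IS over samples; its p-value is the upper-tail probability of that mean
under a null of random gene pairs from the retained universe (default 1000
draws, add-one correction, mandatory seed).

**Consensus and evaluation.** Per-method prediction tables are put on a
common footing via within-method percentile ranks; communications
(ligand, receptor, sender, receiver) predicted by ≥ `min_support` methods
form the consensus, ranked by mean percentile. The consensus set is
evaluated against each method's own ranking with the weighted
Kolmogorov–Smirnov enrichment score (the GSEA statistic, set-membership
permutation p) and with top-50% occupancy — the share of consensus keys in
the method's top half.

A seeded synthetic-data module generates expression matrices with planted
pairs, LR source tables with exact overlap designs, and multi-method
prediction tables, so the whole pipeline runs without any downloads.

## Worked example

```bash
lrcomm simulate expression --seed 11 --n-genes 120 --n-samples 12 \
    --n-planted-pairs 4 --out demo
lrcomm score-bulk --expr demo/expression.tsv --pairs demo/planted_pairs.csv \
    --n-perm 1000 --seed 7 --cancer-type "Skin Cancer" --out demo/scores.csv
# scored 4 pairs (0 skipped); 4 significant at alpha=0.05
cat demo/scores.csv
# ligand,receptor,function,evidence,cancer_type,interaction_strength,p_value
# G00001,G00002,,,Skin Cancer,155.15451388888889,0.001998001998001998
# G00003,G00004,,,Skin Cancer,153.95138888888889,0.001998001998001998
# G00005,G00006,,,Skin Cancer,163.10474537037035,0.001998001998001998
# G00007,G00008,,,Skin Cancer,167.19675925925927,0.001998001998001998
```

The four pairs were planted jointly in the top expression decile of ~80% of
samples, so each reaches a mean interaction strength around 150–170 (out of
200) and the smallest possible p-value at 1000 permutations,
(1 + 1)/1001 ≈ 0.002.

```bash
lrcomm simulate predictions --seed 3 --n-methods 5 --out demo/preds
lrcomm consensus --pred demo/preds/method*.csv --min-support 2 --out demo/consensus.csv
# consensus: 50 communications from 5 methods
lrcomm gsea --list demo/preds/method1.csv --set demo/consensus.csv --n-perm 1000 --seed 9
# ES=0.9492 p=0.000999 occupancy@0.5=1.000
```

The 50 planted communications shared by all five mock methods are recovered
as the consensus; they are strongly enriched toward the top of method 1's
own ranking (ES ≈ 0.95, permutation p ≈ 0.001) and all of them sit in its
top half.

The same functionality is available as a library:

```python
import lrcomm as lc
spec = lc.FixtureSpec(seed=11, n_genes=120, n_samples=12, n_planted_pairs=4)
expr, pairs = lc.make_expression(spec)
run = lc.score_pairs(expr, pairs, n_perm=1000, seed=7)
run.to_frame()
```

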