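"""Rank-based interaction-strength scoring on bulk expression.

The statistic measures how strongly two genes (typically a ligand and its
receptor) are *jointly and similarly highly* expressed across the samples of
a bulk RNA-seq cohort.  Within each sample, every retained gene receives a
normalized rank score r in (0, 10] (10 = most expressed).  For a gene pair
with per-sample scores r1 and r2 the per-sample interaction strength is

    IS = (r1 + r2) * (10 - |r1 - r2|)

so IS is maximal (200) when both genes top the sample and falls off when
either gene is lowly expressed or the two diverge.  The dataset-level
strength is the mean IS over samples, and its significance is the upper-tail
probability of that mean under a null of random gene pairs drawn from the
retained gene universe, scored identically.

Preprocessing follows the standard bulk pipeline: FPKM input, genes with
zeros in more than ``zero_fraction_max`` of samples removed, log2(FPKM+0.05)
normalization for reporting.  Because the statistic depends only on
within-sample ranks, scoring is invariant to any monotone per-sample
transform, including that normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Top rank score; ranks live on the (0, RANK_SCALE] scale.
RANK_SCALE = 10.0
#: Maximal attainable interaction strength, (10 + 10) * (10 - 0).
IS_MAX = 200.0
#: Smallest cohort the statistic is run on.
MIN_SAMPLES = 6
#: Pseudocount added to FPKM before log2 for the normalized view.
LOG_PSEUDOCOUNT = 0.05
DEFAULT_ZERO_FRACTION_MAX = 0.30


def load_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples FPKM table (first column gene IDs).

    TSV or CSV by extension.  Raises on missing values, negative FPKM or
    duplicate gene identifiers.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    validate_expression(df)
    return df


def validate_expression(df: pd.DataFrame) -> None:
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if (df.to_numpy() < 0).any():
        raise ValueError("FPKM values must be non-negative")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups[:5]}")


def normalize_log2(df: pd.DataFrame, pseudocount: float = LOG_PSEUDOCOUNT) -> pd.DataFrame:
    """log2(FPKM + pseudocount) view used for storage and reporting."""
    return np.log2(df + pseudocount)


def filter_genes(
    df: pd.DataFrame, zero_fraction_max: float = DEFAULT_ZERO_FRACTION_MAX
) -> pd.DataFrame:
    """Drop genes whose expression is zero in MORE than ``zero_fraction_max``
    of samples; a gene at exactly the threshold is retained."""
    if df.shape[1] < 1:
        raise ValueError("expression matrix has no samples")
    zero_frac = (df == 0).sum(axis=1) / df.shape[1]
    keep = zero_frac <= zero_fraction_max
    if not keep.any():
        raise ValueError(
            f"all {df.shape[0]} genes removed at zero_fraction_max={zero_fraction_max}"
        )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_genes: dropped %d of %d genes", n_dropped, df.shape[0])
    return df.loc[keep]


def rank_transform(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample normalized rank scores on the (0, 10] scale.

    Genes are ranked in descending order of expression per sample; position
    ``pos`` (1 = highest, average positions for ties) becomes
    ``r = 10 * (G - pos + 1) / G`` for G retained genes, so the top gene
    scores 10 and the bottom gene 10/G.
    """
    n_genes = df.shape[0]
    if n_genes < 2:
        raise ValueError("rank transform needs at least 2 genes")
    x = df.to_numpy(dtype=float)
    # pos 1 = highest expressed; ties get the average position
    pos = np.apply_along_axis(lambda col: rankdata(-col, method="average"), 0, x)
    r = RANK_SCALE * (n_genes - pos + 1.0) / n_genes
    return pd.DataFrame(r, index=df.index, columns=df.columns)


def interaction_strength(r1, r2):
    """IS = (r1 + r2) * (10 - |r1 - r2|); symmetric, in [0, 200].

    Accepts scalars or broadcastable arrays of rank scores in (0, 10];
    values outside that interval signal an unscaled rank and raise.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    for r in (r1, r2):
        if np.any((r <= 0) | (r > RANK_SCALE)):
            raise ValueError("rank scores must lie in (0, 10]")
    out = (r1 + r2) * (RANK_SCALE - np.abs(r1 - r2))
    return float(out) if out.ndim == 0 else out


@dataclass
class InteractionScore:
    """Scored gene pair: per-sample strengths, their mean, permutation p."""

    pair: tuple[str, str]
    per_sample_is: np.ndarray
    summary_is: float
    p_value: float
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


@dataclass
class ScoreRun:
    """Result of one scoring run: scored pairs plus skipped-pair log."""

    scores: list[InteractionScore]
    skipped: list[tuple[tuple[str, str], str]] = field(default_factory=list)
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene1": s.pair[0],
                "gene2": s.pair[1],
                "interaction_strength": s.summary_is,
                "p_value": s.p_value,
                "n_permutations": s.n_permutations,
            }
            for s in self.scores
        ]
        return pd.DataFrame(
            rows,
            columns=["gene1", "gene2", "interaction_strength", "p_value", "n_permutations"],
        )


def _null_pair_indices(
    rng: np.random.Generator, n_genes: int, n_perm: int, forbidden: tuple[int, int] | None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_perm`` random ordered gene-index pairs, two distinct genes per
    draw, excluding the observed pair."""
    a = rng.integers(0, n_genes, size=n_perm)
    b = rng.integers(0, n_genes, size=n_perm)
    bad = a == b
    if forbidden is not None:
        bad |= (a == forbidden[0]) & (b == forbidden[1])
    while bad.any():
        n_bad = int(bad.sum())
        a[bad] = rng.integers(0, n_genes, size=n_bad)
        b[bad] = rng.integers(0, n_genes, size=n_bad)
        bad = a == b
        if forbidden is not None:
            bad |= (a == forbidden[0]) & (b == forbidden[1])
    return a, b


def score_pairs(
    expr: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    *,
    n_perm: int = 1000,
    seed: int,
    zero_fraction_max: float = DEFAULT_ZERO_FRACTION_MAX,
    min_samples: int = MIN_SAMPLES,
    alternative: str = "greater",
    prefiltered: bool = False,
) -> ScoreRun:
    """Score gene pairs on a bulk FPKM matrix with permutation p-values.

    Pairs with a gene absent after filtering are skipped and logged.  For
    each observed pair the null is ``n_perm`` random gene pairs (two distinct
    genes per draw, the observed pair excluded) from the retained universe,
    scored identically, and

        p = (1 + #{null mean IS >= observed mean IS}) / (n_perm + 1)

    (``alternative="less"`` flips the inequality).  The null generator for
    the k-th pair in ``pairs`` is seeded with ``[seed, k]``, so each pair's
    p-value is reproducible independently of list order or length.
    """
    if seed is None:
        raise ValueError("a seed is required for permutation runs")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if expr.shape[1] < min_samples:
        raise ValueError(
            f"dataset has {expr.shape[1]} samples; at least {min_samples} required"
        )
    # ranks only depend on within-sample order, so normalized (possibly
    # negative) input is as valid as raw FPKM; only NaNs and duplicate
    # gene IDs are fatal here
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene identifiers")
    retained = expr if prefiltered else filter_genes(expr, zero_fraction_max)
    ranks = rank_transform(retained)
    r = ranks.to_numpy()
    gene_index = {g: i for i, g in enumerate(ranks.index)}
    n_genes = r.shape[0]

    run = ScoreRun(scores=[], seed=seed)
    for k, (g1, g2) in enumerate(pairs):
        if g1 not in gene_index or g2 not in gene_index:
            missing = [g for g in (g1, g2) if g not in gene_index]
            reason = f"gene(s) absent after filtering: {','.join(missing)}"
            logger.info("skipping pair (%s, %s): %s", g1, g2, reason)
            run.skipped.append(((g1, g2), reason))
            continue
        i, j = gene_index[g1], gene_index[g2]
        per_sample = (r[i] + r[j]) * (RANK_SCALE - np.abs(r[i] - r[j]))
        observed = float(per_sample.mean())

        rng = np.random.default_rng([seed, k])
        a, b = _null_pair_indices(rng, n_genes, n_perm, forbidden=(i, j))
        null_is = (r[a] + r[b]) * (RANK_SCALE - np.abs(r[a] - r[b]))
        null_summary = null_is.mean(axis=1)
        if alternative == "greater":
            n_as_extreme = int((null_summary >= observed).sum())
        else:
            n_as_extreme = int((null_summary <= observed).sum())
        p = (1.0 + n_as_extreme) / (n_perm + 1.0)
        run.scores.append(
            InteractionScore(
                pair=(g1, g2),
                per_sample_is=per_sample,
                summary_is=observed,
                p_value=p,
                n_permutations=n_perm,
                seed=seed,
            )
        )
    return run


def score_reference_sets(
    expr: pd.DataFrame,
    curated_pairs: Sequence[tuple[str, str]],
    lr_pairs: Sequence[tuple[str, str]],
    *,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int,
    **kwargs,
) -> dict[str, dict]:
    """Score both reference pair sets and count significant pairs at ``alpha``.

    ``alpha`` defaults to 0.05; small cohorts conventionally use the more
    permissive 0.1 profile.  Returns, per reference set, the scored table
    and the number/fraction of pairs with p <= alpha.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    out: dict[str, dict] = {}
    for name, ref in (("curated", curated_pairs), ("lr", lr_pairs)):
        if len(ref) == 0:
            raise ValueError(f"reference set {name!r} is empty")
        run = score_pairs(expr, ref, n_perm=n_perm, seed=seed, **kwargs)
        table = run.to_frame()
        # p <= alpha: alpha=1 accepts everything, alpha=0 nothing (p is never 0)
        sig = table["p_value"] <= alpha
        out[name] = {
            "table": table,
            "n_scored": len(table),
            "n_significant": int(sig.sum()),
            "frac_significant": float(sig.mean()) if len(table) else float("nan"),
            "alpha": alpha,
            "skipped": run.skipped,
        }
    return out
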