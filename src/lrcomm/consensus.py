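"""Consensus integration and enrichment-based evaluation of cell-cell
communication predictions.

Several single-cell algorithms (e.g. iTALK, CellTalker, ICELLNET, NicheNet)
predict ligand -> receptor communications between a sender and a receiver
cell type, each with a method-native communication score.  Those scores are
not comparable across methods, so each record first receives a *within-
method percentile rank* in [0, 1].  Communications are then grouped by the
shared key (ligand, receptor, sender, receiver) and integrated by support
count: a consensus communication is one predicted by at least ``min_support``
methods, ranked by the mean of its within-method percentiles.

The consensus set is evaluated against each individual method with the
classic weighted Kolmogorov-Smirnov running-sum enrichment score (the GSEA
statistic, permutation of set membership) and with top-fraction occupancy:
the share of consensus keys landing in the top half of a method's own
ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Communication key fields, in order.
KEY_FIELDS = ("ligand", "receptor", "sender_cell", "receiver_cell")

Key = tuple[str, str, str, str]


@dataclass(frozen=True)
class PredictionRecord:
    """One method's predicted communication with its native score."""

    ligand: str
    receptor: str
    sender_cell: str
    receiver_cell: str
    method: str
    communication_score: float
    dataset: str = ""
    percentile_rank: float = float("nan")

    @property
    def key(self) -> Key:
        return (self.ligand, self.receptor, self.sender_cell, self.receiver_cell)


@dataclass(frozen=True)
class ConsensusResult:
    key: Key
    support: int
    methods: tuple[str, ...]
    per_method_percentile: Mapping[str, float]
    consensus_rank: float


def _percentile_ranks(scores: np.ndarray) -> np.ndarray:
    """Within-method percentile in (0, 1]: rank/n, average ties, top score -> 1."""
    order = pd.Series(scores).rank(method="average", ascending=True)
    return (order / len(scores)).to_numpy()


def load_predictions(
    paths: Sequence[str | Path],
    method_names: Sequence[str],
    *,
    column_map: Mapping[str, str] | None = None,
    dataset: str = "",
) -> list[PredictionRecord]:
    """Read one CSV per method into normalized prediction records.

    ``column_map`` maps the canonical columns (``ligand``, ``receptor``,
    ``sender_cell``, ``receiver_cell``, ``score``) to the files' headers.
    Rows with non-numeric scores are rejected with a logged reason; a
    duplicate key within one method's file is an error; a method
    contributing zero valid rows is an error.
    """
    if len(paths) != len(method_names):
        raise ValueError("paths and method_names differ in length")
    colmap = {c: c for c in (*KEY_FIELDS, "score")}
    if column_map:
        colmap.update(column_map)
    records: list[PredictionRecord] = []
    for path, method in zip(paths, method_names):
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for canon in (*KEY_FIELDS, "score"):
            if colmap[canon] not in df.columns:
                raise ValueError(
                    f"method {method}: missing column {colmap[canon]!r} in {path}"
                )
        rows: list[tuple[Key, float]] = []
        seen: set[Key] = set()
        for idx, row in df.iterrows():
            key: Key = tuple(str(row[colmap[f]]).strip() for f in KEY_FIELDS)  # type: ignore[assignment]
            try:
                score = float(row[colmap["score"]])
            except ValueError:
                logger.info(
                    "method %s row %d: non-numeric score %r, row rejected",
                    method, idx, row[colmap["score"]],
                )
                continue
            if key in seen:
                raise ValueError(f"method {method}: duplicate key {key} in {path}")
            seen.add(key)
            rows.append((key, score))
        if not rows:
            raise ValueError(f"method {method}: no valid rows in {path}")
        pct = _percentile_ranks(np.array([s for _, s in rows]))
        for (key, score), p in zip(rows, pct):
            records.append(
                PredictionRecord(
                    *key,
                    method=method,
                    communication_score=score,
                    dataset=dataset,
                    percentile_rank=float(p),
                )
            )
    return records


def integrate_predictions(
    records: Sequence[PredictionRecord], min_support: int = 2
) -> list[ConsensusResult]:
    """Support-count consensus over per-method predictions.

    Groups records by communication key; keeps keys predicted by at least
    ``min_support`` methods; consensus_rank is the mean within-method
    percentile over the supporting methods.  Output order is deterministic:
    support desc, consensus_rank desc, key lexicographic.
    """
    methods = sorted({r.method for r in records})
    if len(methods) < 2:
        raise ValueError("integration requires predictions from at least 2 methods")
    if min_support > len(methods):
        raise ValueError(
            f"min_support={min_support} exceeds the {len(methods)} methods supplied"
        )
    grouped: dict[Key, dict[str, float]] = {}
    for r in records:
        grouped.setdefault(r.key, {})[r.method] = r.percentile_rank
    out = []
    for key, per_method in grouped.items():
        if len(per_method) < min_support:
            continue
        ordered = dict(sorted(per_method.items()))  # fixed order: float sum is input-order invariant
        out.append(
            ConsensusResult(
                key=key,
                support=len(ordered),
                methods=tuple(ordered),
                per_method_percentile=ordered,
                consensus_rank=float(np.mean(list(ordered.values()))),
            )
        )
    out.sort(key=lambda c: (-c.support, -c.consensus_rank, c.key))
    return out


def consensus_to_frame(results: Sequence[ConsensusResult]) -> pd.DataFrame:
    rows = [
        {
            **dict(zip(KEY_FIELDS, c.key)),
            "support": c.support,
            "methods": ";".join(c.methods),
            "consensus_rank": c.consensus_rank,
        }
        for c in results
    ]
    return pd.DataFrame(
        rows, columns=[*KEY_FIELDS, "support", "methods", "consensus_rank"]
    )


# ---------------------------------------------------------------------------
# Enrichment of a key set in a score-ranked list (weighted KS running sum)
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    es: float
    p_value: float
    set_size: int
    list_size: int
    leading_edge: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.es) > 1 + 1e-12:
            raise ValueError(f"|ES| = {abs(self.es)} exceeds 1")


def _running_es(
    in_set: np.ndarray, weights: np.ndarray
) -> tuple[float, int, np.ndarray]:
    """ES and extremum position for a 0/1 membership vector over a ranked
    list with per-position hit weights (already |score|^exponent)."""
    n = in_set.size
    n_hit = int(in_set.sum())
    n_miss = n - n_hit
    hit_mask = in_set.astype(bool)
    w = weights
    wmax = float(np.max(w)) if w.size else 0.0
    if wmax > 0:  # rescale before normalizing to dodge overflow on tiny weights
        w = w / wmax
    hit_total = float(w[hit_mask].sum())
    if hit_total > 1e-12:
        hit_step = w / hit_total
    else:  # all in-set weights (numerically) zero: fall back to unweighted hits
        hit_step = np.full(n, 1.0 / n_hit)
    step = np.where(hit_mask, hit_step, (-1.0 / n_miss) if n_miss > 0 else 0.0)
    running = np.cumsum(step)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = float(running[i_max]) if running[i_max] >= -running[i_min] else float(running[i_min])
    i_ext = i_max if running[i_max] >= -running[i_min] else i_min
    return es, i_ext, running


def enrichment_score(
    ranked_list: Sequence[tuple[object, float]] | pd.Series,
    gene_set: set,
    *,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Weighted Kolmogorov-Smirnov enrichment of ``gene_set`` in a ranked list.

    ``ranked_list`` is keys with scores, already ordered by score descending
    (a pandas Series ``key -> score`` or a sequence of ``(key, score)``).
    Walking down the list, hits increment the running sum by
    ``|score|^weight_exponent`` normalized over in-set scores and misses
    decrement by ``1/(N - Nh)``; ES is the extremum.  The p-value compares ES
    against ``n_perm`` random same-size key sets drawn from the list
    (membership permutation), one-sided on the observed sign, with an
    add-one correction.
    """
    if isinstance(ranked_list, pd.Series):
        keys = list(ranked_list.index)
        scores = ranked_list.to_numpy(dtype=float)
    else:
        keys = [k for k, _ in ranked_list]
        scores = np.array([s for _, s in ranked_list], dtype=float)
    if len(set(keys)) != len(keys):
        raise ValueError("ranked list contains duplicate keys")
    in_set = np.array([k in gene_set for k in keys], dtype=float)
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene_set does not intersect the ranked list")
    weights = np.abs(scores) ** weight_exponent

    es, i_ext, running = _running_es(in_set, weights)
    hit_idx = np.flatnonzero(in_set)
    if es >= 0:
        leading = [keys[i] for i in hit_idx if i <= i_ext]
    else:
        leading = [keys[i] for i in hit_idx if i >= i_ext]

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(keys)
    null_es = np.empty(n_perm)
    membership = np.zeros(n)
    for t in range(n_perm):
        membership[:] = 0.0
        membership[rng.choice(n, size=n_hit, replace=False)] = 1.0
        null_es[t], _, _ = _running_es(membership, weights)
    if es >= 0:
        p = (1.0 + float((null_es >= es).sum())) / (n_perm + 1.0)
    else:
        p = (1.0 + float((null_es <= es).sum())) / (n_perm + 1.0)
    return EnrichmentResult(
        es=es, p_value=p, set_size=n_hit, list_size=n, leading_edge=leading
    )


def top_fraction_occupancy(
    ranked_list: Sequence | pd.Series, gene_set: set, fraction: float = 0.5
) -> float:
    """Share of the set's in-list keys that land in the top ``fraction``.

    ``ranked_list`` is keys ordered by score descending (scores, if present
    as ``(key, score)`` tuples or a Series, are ignored beyond the order).
    Top-k is ``k = ceil(fraction * N)``.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if isinstance(ranked_list, pd.Series):
        keys = list(ranked_list.index)
    else:
        items = list(ranked_list)
        # accept bare keys or the (key, score) pairs enrichment_score takes
        if items and all(
            isinstance(k, tuple) and len(k) == 2 and isinstance(k[1], (int, float, np.floating))
            for k in items
        ):
            keys = [k for k, _ in items]
        else:
            keys = items
    in_list = [k for k in keys if k in gene_set]
    if not in_list:
        raise ValueError("gene_set does not intersect the ranked list")
    k_top = math.ceil(fraction * len(keys))
    top = set(keys[:k_top])
    return sum(1 for k in in_list if k in top) / len(in_list)
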