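"""Synthetic inputs with the statistical structure the methods assume.

Three generators cover the three data domains:

* :func:`make_expression` — a bulk FPKM matrix (log-normal background,
  optional per-entry zero inflation so the zero-fraction gene filter has
  work to do) with *planted* gene pairs forced into the top expression
  quantile of a configurable fraction of samples.  Planting acts on
  quantiles, not additive shifts, because the interaction-strength
  statistic is rank-based and only quantiles matter.
* :func:`make_lr_catalogs` — per-source LR tables whose exclusive subset
  intersections exactly match a requested overlap design, for exercising
  catalog merging and UpSet-style counting.
* :func:`make_predictions` — per-method communication tables built from a
  shared planted core (scored from a high distribution) plus method-specific
  noise (scored lower), the structure consensus integration is meant to
  exploit.

Everything is driven by ``numpy.random.default_rng(seed)``: identical spec
and seed give byte-identical CSV output.  These fixtures emulate rank and
overlap structure only — no library-size, batch or dropout realism — so
tests passing on them demonstrate algorithmic correctness, not performance
on real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import FUNCTIONAL_GROUPS


@dataclass
class FixtureSpec:
    """Parameters for the synthetic generators; ``seed`` is mandatory."""

    seed: int
    # expression
    n_genes: int = 200
    n_samples: int = 20
    n_planted_pairs: int = 0
    planted_quantile: float = 0.9
    planted_sample_fraction: float = 0.8
    zero_inflation: float = 0.0
    background_meanlog: float = 1.0
    background_sdlog: float = 1.0
    # predictions
    n_methods: int = 5
    n_shared_predictions: int = 50
    n_noise_predictions: int = 100
    shared_score_loc: float = 0.75
    noise_score_loc: float = 0.30
    score_scale: float = 0.12
    # LR catalogs
    n_sources: int = 3
    overlap: Mapping[tuple[str, ...], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("FixtureSpec.seed is mandatory")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_samples < 6:
            raise ValueError("n_samples must be >= 6")
        if not (0.0 <= self.zero_inflation < 1.0):
            raise ValueError("zero_inflation must lie in [0, 1)")
        if not (0.0 < self.planted_quantile <= 1.0):
            raise ValueError("planted_quantile must lie in (0, 1]")
        if 2 * self.n_planted_pairs > self.n_genes:
            raise ValueError("planted pairs need 2 genes each within n_genes")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def make_expression(spec: FixtureSpec) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Bulk FPKM matrix plus the manifest of planted pair keys.

    Background FPKM is log-normal (meanlog/sdlog from the spec); each entry
    is independently zeroed with probability ``zero_inflation``.  Each
    planted pair takes two dedicated genes; in a ``planted_sample_fraction``
    share of samples (chosen per pair) both genes are raised just above the
    sample's ``planted_quantile`` expression quantile, with a deterministic
    offset so planted genes of one sample stay distinct.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    samples = [f"S{j:03d}" for j in range(1, spec.n_samples + 1)]
    x = rng.lognormal(
        mean=spec.background_meanlog,
        sigma=spec.background_sdlog,
        size=(spec.n_genes, spec.n_samples),
    )
    if spec.zero_inflation > 0:
        x[rng.random(x.shape) < spec.zero_inflation] = 0.0

    manifest: list[tuple[str, str]] = []
    for p in range(spec.n_planted_pairs):
        i1, i2 = 2 * p, 2 * p + 1
        manifest.append((genes[i1], genes[i2]))
        n_hot = int(round(spec.planted_sample_fraction * spec.n_samples))
        hot = rng.choice(spec.n_samples, size=n_hot, replace=False)
        for j in hot:
            q = float(np.quantile(x[:, j], spec.planted_quantile))
            # both genes just above the quantile, tied with each other so the
            # pair's rank gap is 0; pair-specific offsets order distinct pairs
            x[i1, j] = q * (1.0 + 0.01 * (p + 1))
            x[i2, j] = x[i1, j]
    df = pd.DataFrame(x, index=genes, columns=samples)
    df.index.name = "gene"
    return df, manifest


# ---------------------------------------------------------------------------
# LR source catalogs with an exact overlap design
# ---------------------------------------------------------------------------

def make_lr_catalogs(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> tuple[dict[str, pd.DataFrame], dict[tuple[str, ...], list[tuple[str, str]]]]:
    """Per-source LR tables realizing an exact exclusive-overlap design.

    ``spec.overlap`` maps a tuple of source names to the number of pairs
    present in *exactly* those sources.  When empty, a default design over
    ``n_sources`` sources is used: 5 pairs exclusive to each source, 3 in
    every adjacent 2-subset, and 2 shared by all.  Returns per-source
    DataFrames (columns ligand, receptor, evidence) and the truth manifest
    subset -> pair keys; if ``out_dir`` is given, also writes
    ``<source>.csv`` files there.
    """
    if spec.overlap:
        overlap = {tuple(k): int(v) for k, v in spec.overlap.items()}
        sources = sorted({s for sub in overlap for s in sub})
    else:
        sources = [f"src{c}" for c in "ABCDEFG"[: spec.n_sources]]
        overlap = {(s,): 5 for s in sources}
        for a, b in zip(sources, sources[1:]):
            overlap[(a, b)] = 3
        overlap[tuple(sources)] = overlap.get(tuple(sources), 0) + 2
    if len(sources) < 2:
        raise ValueError("overlap design must involve >= 2 sources")
    for sub, n in overlap.items():
        if n < 0:
            raise ValueError(f"negative count for subset {sub}")
        if not set(sub) <= set(sources):
            raise ValueError(f"subset {sub} mentions unknown sources")

    rng = np.random.default_rng(spec.seed)
    total = sum(overlap.values())
    ligands = [f"L{i:04d}" for i in range(1, total + 1)]
    receptors = [f"R{i:04d}" for i in range(1, total + 1)]
    order = rng.permutation(total)
    pool = [(ligands[i], receptors[i]) for i in order]

    manifest: dict[tuple[str, ...], list[tuple[str, str]]] = {}
    per_source: dict[str, list[tuple[str, str]]] = {s: [] for s in sources}
    cursor = 0
    for sub in sorted(overlap, key=lambda t: (len(t), t)):
        n = overlap[sub]
        chunk = pool[cursor : cursor + n]
        cursor += n
        manifest[sub] = chunk
        for s in sub:
            per_source[s].extend(chunk)

    frames: dict[str, pd.DataFrame] = {}
    for s in sources:
        pairs = sorted(per_source[s])
        ev = ["curated" if rng.random() < 0.5 else "predicted" for _ in pairs]
        frames[s] = pd.DataFrame(
            {
                "ligand": [p[0] for p in pairs],
                "receptor": [p[1] for p in pairs],
                "evidence": ev,
            }
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s, df in frames.items():
            df.to_csv(out_dir / f"{s}.csv", index=False)
    return frames, manifest


def make_group_annotation(
    genes: Sequence[str], seed: int, groups: Sequence[str] = FUNCTIONAL_GROUPS,
    p_annotated: float = 0.7,
) -> dict[str, set[str]]:
    """Random gene -> functional-group map over the 10-group vocabulary."""
    rng = np.random.default_rng(seed)
    ann: dict[str, set[str]] = {}
    for g in genes:
        if rng.random() < p_annotated:
            k = int(rng.integers(1, 3))
            ann[g] = set(rng.choice(list(groups), size=k, replace=False))
    return ann


# ---------------------------------------------------------------------------
# Multi-method prediction tables
# ---------------------------------------------------------------------------

_CELLS = ("Tumor", "Tcell", "Bcell", "NK", "Macrophage", "DC")


def make_predictions(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> tuple[dict[str, pd.DataFrame], list[tuple[str, str, str, str]]]:
    """Per-method prediction tables with a planted shared core.

    Every method reports all ``n_shared_predictions`` planted communications
    with scores from a high normal (loc ``shared_score_loc``) and its own
    ``n_noise_predictions`` method-specific communications scored from a
    lower normal (loc ``noise_score_loc``).  Returns per-method DataFrames
    (columns ligand, receptor, sender_cell, receiver_cell, score) and the
    manifest of planted keys; optionally writes ``<method>.csv`` files.
    """
    if spec.n_methods < 2:
        raise ValueError("n_methods must be >= 2")
    rng = np.random.default_rng(spec.seed)
    methods = [f"method{i}" for i in range(1, spec.n_methods + 1)]

    def _key(tag: str, i: int) -> tuple[str, str, str, str]:
        sender = _CELLS[i % len(_CELLS)]
        receiver = _CELLS[(i + 1) % len(_CELLS)]
        return (f"LIG_{tag}{i:04d}", f"REC_{tag}{i:04d}", sender, receiver)

    planted = [_key("core", i) for i in range(spec.n_shared_predictions)]
    frames: dict[str, pd.DataFrame] = {}
    for m_idx, m in enumerate(methods):
        shared_scores = rng.normal(
            spec.shared_score_loc, spec.score_scale, size=len(planted)
        )
        noise_keys = [
            _key(f"m{m_idx}n", i) for i in range(spec.n_noise_predictions)
        ]
        noise_scores = rng.normal(
            spec.noise_score_loc, spec.score_scale, size=len(noise_keys)
        )
        keys = planted + noise_keys
        scores = np.concatenate([shared_scores, noise_scores])
        frames[m] = pd.DataFrame(
            {
                "ligand": [k[0] for k in keys],
                "receptor": [k[1] for k in keys],
                "sender_cell": [k[2] for k in keys],
                "receiver_cell": [k[3] for k in keys],
                "score": np.round(scores, 6),
            }
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for m, df in frames.items():
            df.to_csv(out_dir / f"{m}.csv", index=False)
    return frames, planted
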