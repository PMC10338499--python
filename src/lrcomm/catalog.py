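"""Ligand-receptor catalog integration and functional classification.

A ligand-receptor (LR) pair is an *ordered* gene pair: the ligand is the
molecule released or displayed by a sender cell, the receptor sits on the
receiver cell, so (A, B) and (B, A) are distinct pairs.  Public LR resources
disagree on coverage and on how pairs were identified; this module harmonizes
per-source tables into one deduplicated catalog per species, tracks
provenance (which sources list a pair) and an evidence subclass
(``manually_curated`` if at least one source has experimental/manual support,
``predicted`` otherwise), classifies pairs into ten immune-signaling
functional groups from GO-derived gene annotations, and computes UpSet-style
exclusive intersection counts across sources.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The ten functional groups, in canonical priority order (first wins when a
#: pair matches several groups).
FUNCTIONAL_GROUPS: tuple[str, ...] = (
    "notch signaling",
    "antigen binding",
    "neuropeptide",
    "hormone",
    "growth factor",
    "interferon",
    "interleukin",
    "tumor necrosis factor",
    "chemokine",
    "cytokine",
)

#: Label for pairs matching no functional group.
OTHER_GROUP = "other"

SPECIES = ("human", "mouse")

EVIDENCE_CURATED = "manually_curated"
EVIDENCE_PREDICTED = "predicted"


class SchemaError(ValueError):
    """A required column is missing or a controlled vocabulary is violated."""


@dataclass(frozen=True)
class LRPair:
    """One ligand-receptor pair with provenance and functional annotation.

    ``ligand_id`` / ``receptor_id`` are the canonical keys (Ensembl gene IDs
    when a symbol-to-Ensembl map is supplied, otherwise the symbols as given,
    flagged via ``unmapped``).  ``sources`` is the set of source datasets that
    list the pair; it is never empty.
    """

    ligand_id: str
    receptor_id: str
    species: str
    sources: frozenset[str]
    evidence: str = EVIDENCE_PREDICTED
    primary_group: str = OTHER_GROUP
    all_groups: frozenset[str] = frozenset()
    ligand_symbol: str | None = None
    receptor_symbol: str | None = None
    unmapped: bool = False
    complex_note: str = ""

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if not self.sources:
            raise ValueError("LRPair.sources must be non-empty")
        if self.evidence not in (EVIDENCE_CURATED, EVIDENCE_PREDICTED):
            raise ValueError(f"unknown evidence subclass {self.evidence!r}")
        if (self.primary_group == OTHER_GROUP) != (not self.all_groups):
            raise ValueError("primary_group is 'other' iff all_groups is empty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.ligand_id, self.receptor_id)


@dataclass
class LRCatalog:
    """A deduplicated set of LR pairs of one species.

    ``pairs`` maps ``(ligand_id, receptor_id)`` to the pair record;
    ``source_names`` preserves the order sources were contributed in.
    """

    species: str
    pairs: dict[tuple[str, str], LRPair] = field(default_factory=dict)
    source_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.pairs

    def __iter__(self):
        return iter(self.pairs.values())

    def add(self, pair: LRPair) -> None:
        if pair.species != self.species:
            raise ValueError(
                f"cannot add {pair.species} pair to a {self.species} catalog"
            )
        existing = self.pairs.get(pair.key)
        self.pairs[pair.key] = pair if existing is None else _combine(existing, pair)
        for s in sorted(pair.sources):
            if s not in self.source_names:
                self.source_names.append(s)

    def keys(self) -> set[tuple[str, str]]:
        return set(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view in the integrated-interactions column order."""
        rows = [
            {
                "ligand": p.ligand_symbol or p.ligand_id,
                "receptor": p.receptor_symbol or p.receptor_id,
                "ligand_id": p.ligand_id,
                "receptor_id": p.receptor_id,
                "species": p.species,
                "function": p.primary_group,
                "all_functions": ";".join(sorted(p.all_groups)),
                "sources": ";".join(sorted(p.sources)),
                "evidence": p.evidence,
            }
            for p in sorted(self.pairs.values(), key=lambda q: q.key)
        ]
        cols = [
            "ligand", "receptor", "ligand_id", "receptor_id", "species",
            "function", "all_functions", "sources", "evidence",
        ]
        return pd.DataFrame(rows, columns=cols)


def _combine(a: LRPair, b: LRPair) -> LRPair:
    """Merge two records of the same (ligand, receptor, species) key."""
    evidence = (
        EVIDENCE_CURATED
        if EVIDENCE_CURATED in (a.evidence, b.evidence)
        else EVIDENCE_PREDICTED
    )
    groups = a.all_groups | b.all_groups
    primary = a.primary_group if a.all_groups else b.primary_group
    return replace(
        a,
        sources=a.sources | b.sources,
        evidence=evidence,
        all_groups=groups,
        primary_group=primary if groups else OTHER_GROUP,
        ligand_symbol=a.ligand_symbol or b.ligand_symbol,
        receptor_symbol=a.receptor_symbol or b.receptor_symbol,
        unmapped=a.unmapped and b.unmapped,
        complex_note=a.complex_note or b.complex_note,
    )


# ---------------------------------------------------------------------------
# Loading per-source tables
# ---------------------------------------------------------------------------

@dataclass
class LoadReport:
    """Row accounting for one source file."""

    source_name: str
    n_rows: int = 0
    n_pairs: int = 0
    n_duplicates: int = 0
    n_unmapped: int = 0
    n_malformed: int = 0


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    try:
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def load_lr_source(
    path: str | Path,
    source_name: str,
    species: str,
    *,
    column_map: Mapping[str, str] | None = None,
    default_evidence: str = EVIDENCE_PREDICTED,
    id_map: Mapping[str, str] | None = None,
) -> tuple[LRCatalog, LoadReport]:
    """Read one source's LR table into a catalog.

    Parameters
    ----------
    column_map
        Maps the canonical names ``ligand``, ``receptor`` and optionally
        ``evidence`` to the file's actual column headers.
    default_evidence
        Evidence subclass assigned to every pair when the file has no
        evidence column; sources are typically curated or predicted as a
        whole, at the level of their identification method.
    id_map
        Optional symbol-to-Ensembl map.  Genes absent from the map keep
        their symbol and the pair is flagged ``unmapped``.

    Returns the catalog and a :class:`LoadReport` counting rows, duplicates
    and unmapped/malformed rows.  An empty file yields an empty catalog with
    a warning, not an error.
    """
    colmap = {"ligand": "ligand", "receptor": "receptor", "evidence": "evidence"}
    if column_map:
        colmap.update(column_map)
    df = _read_table(path)
    report = LoadReport(source_name=source_name, n_rows=len(df))
    catalog = LRCatalog(species=species)
    if df.empty and df.columns.empty:
        logger.warning("source %s: file %s is empty; empty catalog", source_name, path)
        return catalog, report
    for role in ("ligand", "receptor"):
        if colmap[role] not in df.columns:
            raise SchemaError(
                f"source {source_name}: missing required column {colmap[role]!r} "
                f"(mapped from {role!r}); found {list(df.columns)}"
            )
    has_evidence = colmap["evidence"] in df.columns

    for idx, row in df.iterrows():
        lig_sym = str(row[colmap["ligand"]]).strip()
        rec_sym = str(row[colmap["receptor"]]).strip()
        if not lig_sym or not rec_sym:
            report.n_malformed += 1
            logger.info("source %s row %d: blank gene field, retained as malformed", source_name, idx)
            continue
        unmapped = False
        if id_map is not None:
            lig_id = id_map.get(lig_sym)
            rec_id = id_map.get(rec_sym)
            if lig_id is None or rec_id is None:
                unmapped = True
                report.n_unmapped += 1
            lig_id = lig_id or lig_sym
            rec_id = rec_id or rec_sym
        else:
            lig_id, rec_id = lig_sym, rec_sym
        if has_evidence:
            raw = str(row[colmap["evidence"]]).strip().lower()
            evidence = (
                EVIDENCE_CURATED
                if raw in ("curated", "manually_curated", "manually curated", "experimental")
                else EVIDENCE_PREDICTED
            )
        else:
            evidence = default_evidence
        key = (lig_id, rec_id)
        if key in catalog:
            report.n_duplicates += 1
        catalog.add(
            LRPair(
                ligand_id=lig_id,
                receptor_id=rec_id,
                species=species,
                sources=frozenset({source_name}),
                evidence=evidence,
                ligand_symbol=lig_sym,
                receptor_symbol=rec_sym,
                unmapped=unmapped,
            )
        )
    report.n_pairs = len(catalog)
    return catalog, report


def merge_catalogs(catalogs: Sequence[LRCatalog]) -> LRCatalog:
    """Union catalogs of one species.

    Sources accumulate; a pair is ``manually_curated`` if any contributing
    source marks it curated.  The merge is idempotent, commutative and
    associative over the pair set.
    """
    if not catalogs:
        raise ValueError("merge_catalogs requires at least one catalog")
    species = {c.species for c in catalogs}
    if len(species) > 1:
        raise ValueError(f"cannot merge catalogs of mixed species {sorted(species)}")
    merged = LRCatalog(species=catalogs[0].species)
    for cat in catalogs:
        for name in cat.source_names:
            if name not in merged.source_names:
                merged.source_names.append(name)
        for pair in cat:
            merged.add(pair)
    return merged


# ---------------------------------------------------------------------------
# Functional classification
# ---------------------------------------------------------------------------

class GroupAnnotation:
    """gene_id -> set of functional-group labels, from GO-derived gene sets.

    Labels are restricted to :data:`FUNCTIONAL_GROUPS`.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None) -> None:
        self._map: dict[str, frozenset[str]] = {}
        if mapping:
            for gene, groups in mapping.items():
                self.add(gene, groups)

    def add(self, gene: str, groups: Iterable[str]) -> None:
        groups = frozenset(g.strip().lower() for g in groups)
        bad = groups - set(FUNCTIONAL_GROUPS)
        if bad:
            raise SchemaError(
                f"unknown functional group(s) {sorted(bad)} for gene {gene!r}; "
                f"vocabulary: {list(FUNCTIONAL_GROUPS)}"
            )
        self._map[gene] = self._map.get(gene, frozenset()) | groups

    def groups_of(self, gene: str) -> frozenset[str]:
        return self._map.get(gene, frozenset())

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GroupAnnotation":
        """Read a GMT file: one group per line, ``name<TAB>desc<TAB>gene...``."""
        ann = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise SchemaError(f"GMT line has <3 fields: {line[:60]!r}")
            group = fields[0]
            for gene in fields[2:]:
                if gene:
                    ann.add(gene, {group})
        return ann

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupAnnotation":
        """Read a two-column TSV ``gene<TAB>group`` (header optional)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        cols = [c.lower() for c in df.columns]
        if cols[:2] != ["gene", "group"]:
            # headerless: first row is data
            df = pd.read_csv(
                path, sep="\t", dtype=str, keep_default_na=False,
                header=None, names=["gene", "group"],
            )
        ann = cls()
        for _, row in df.iterrows():
            ann.add(str(row["gene"]), {str(row["group"])})
        return ann


def classify_pair(
    pair: LRPair,
    annot: GroupAnnotation,
    priority: Sequence[str] = FUNCTIONAL_GROUPS,
) -> LRPair:
    """Assign functional groups to a pair.

    A pair belongs to a group only when *both* the ligand and the receptor
    are annotated to it; ``primary_group`` is the first such group in
    ``priority``, or ``"other"`` when the intersection is empty.  Genes
    absent from the annotation contribute no groups.
    """
    if sorted(priority) != sorted(FUNCTIONAL_GROUPS):
        raise ValueError("priority must be a permutation of the 10-group vocabulary")
    lig_groups = annot.groups_of(pair.ligand_id) | (
        annot.groups_of(pair.ligand_symbol) if pair.ligand_symbol else frozenset()
    )
    rec_groups = annot.groups_of(pair.receptor_id) | (
        annot.groups_of(pair.receptor_symbol) if pair.receptor_symbol else frozenset()
    )
    for gene, groups in ((pair.ligand_id, lig_groups), (pair.receptor_id, rec_groups)):
        if not groups:
            logger.debug("gene %s absent from annotation map; contributes no group", gene)
    shared = lig_groups & rec_groups
    if shared:
        primary = next(g for g in priority if g in shared)
    else:
        primary = OTHER_GROUP
    return replace(pair, all_groups=frozenset(shared), primary_group=primary)


def classify_catalog(
    catalog: LRCatalog,
    annot: GroupAnnotation,
    priority: Sequence[str] = FUNCTIONAL_GROUPS,
) -> LRCatalog:
    out = LRCatalog(species=catalog.species, source_names=list(catalog.source_names))
    for pair in catalog:
        out.pairs[pair.key] = classify_pair(pair, annot, priority)
    return out


# ---------------------------------------------------------------------------
# Cross-source intersection statistics (UpSet semantics)
# ---------------------------------------------------------------------------

@dataclass
class IntersectionStats:
    """Exclusive subset counts over source catalogs.

    ``exclusive[S]`` is the number of pairs present in exactly the sources in
    subset ``S``; exclusive counts over all non-empty subsets partition the
    merged catalog.  ``totals`` are plain per-source sizes and
    ``shared_by_all`` the full intersection.
    """

    source_names: list[str]
    exclusive: dict[frozenset[str], int]
    totals: dict[str, int]
    shared_by_all: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sources": ";".join(sorted(s)), "degree": len(s), "count": c}
            for s, c in self.exclusive.items()
        ]
        df = pd.DataFrame(rows, columns=["sources", "degree", "count"])
        return df.sort_values(
            ["degree", "count", "sources"], ascending=[False, False, True]
        ).reset_index(drop=True)


def intersection_stats(catalogs: Sequence[LRCatalog]) -> IntersectionStats:
    """Count pairs by the exact subset of sources containing them.

    Requires ≥2 catalogs of one species.  Membership is attributed per
    *catalog* (each input catalog is one source column); catalogs should be
    single-source as produced by :func:`load_lr_source`.
    """
    if len(catalogs) < 2:
        raise ValueError("intersection_stats requires at least 2 catalogs")
    species = {c.species for c in catalogs}
    if len(species) > 1:
        raise ValueError(f"mixed species {sorted(species)}")
    names: list[str] = []
    for i, cat in enumerate(catalogs):
        name = cat.source_names[0] if cat.source_names else f"source_{i}"
        names.append(name)
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate source names among catalogs: {names}")

    membership: dict[tuple[str, str], set[str]] = {}
    for name, cat in zip(names, catalogs):
        for key in cat.keys():
            membership.setdefault(key, set()).add(name)
    exclusive: dict[frozenset[str], int] = {
        frozenset(sub): 0
        for r in range(1, len(names) + 1)
        for sub in itertools.combinations(names, r)
    }
    for subset in membership.values():
        exclusive[frozenset(subset)] += 1
    totals = {name: len(cat) for name, cat in zip(names, catalogs)}
    shared_by_all = exclusive[frozenset(names)]
    return IntersectionStats(
        source_names=names,
        exclusive=exclusive,
        totals=totals,
        shared_by_all=shared_by_all,
    )
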