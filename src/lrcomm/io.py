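"""Readers/writers for the resource's CSV table schemas, the curated
tumor-immune interaction data model, and run configuration.

Five table families are supported, mirroring the downloadable CSV layout of
the database the toolkit feeds: the curated (experimentally verified)
interaction table, the integrated ligand-receptor table, bulk predictions
against the curated and LR references, and single-cell consensus
predictions.  All CSVs are comma-separated UTF-8 with RFC-4180 quoting and
a fixed, byte-stable column order per schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .catalog import FUNCTIONAL_GROUPS

logger = logging.getLogger(__name__)

#: The three curated interaction categories: physical tumor-immune contact,
#: secreted molecule -> receptor signaling, and intracellular interactions
#: essential to tumor immunity.
INTERACTION_TYPES = ("direct", "secretory", "indirect")

#: Immune-cell vocabulary shipped as an editable default (14 labels).
IMMUNE_CELLS = (
    "T cell",
    "CD4+ T cell",
    "CD8+ T cell",
    "regulatory T cell",
    "B cell",
    "NK cell",
    "NKT cell",
    "macrophage",
    "monocyte",
    "dendritic cell",
    "neutrophil",
    "mast cell",
    "myeloid-derived suppressor cell",
    "eosinophil",
)

#: Output schema name -> ordered column list.
SCHEMAS: dict[str, list[str]] = {
    "curated": [
        "gene1", "gene2", "tumor_cell", "immune_cell", "interaction_type",
        "species", "cancer_type", "cancer_subtype", "experiment",
        "description", "pmid",
    ],
    "integrated_lr": ["ligand", "receptor", "function", "sources", "evidence"],
    "predicted_bulk_curated": [
        "gene1", "gene2", "tumor_cell", "immune_cell", "cancer_type",
        "interaction_strength", "p_value",
    ],
    "predicted_bulk_lr": [
        "ligand", "receptor", "function", "evidence", "cancer_type",
        "interaction_strength", "p_value",
    ],
    "predicted_scrna": [
        "ligand", "receptor", "sender_cell", "receiver_cell", "methods",
        "support", "consensus_rank", "dataset", "cancer_type",
    ],
}


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class CuratedInteraction:
    """One experimentally verified tumor-immune interaction record."""

    gene1: str
    gene2: str
    tumor_cell: str
    immune_cell: str
    interaction_type: str
    species: str
    cancer_type: str = ""
    cancer_subtype: str = ""
    experiment: str = ""
    description: str = ""
    pmid: int | None = None

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(
                f"interaction_type {self.interaction_type!r} not in {INTERACTION_TYPES}"
            )
        if self.pmid is not None and self.pmid <= 0:
            raise ValueError(f"PMID must be a positive integer, got {self.pmid}")


@dataclass
class CuratedSummary:
    """Counts by category / cancer type / immune cell."""

    by_type: dict[str, int]
    by_cancer: dict[str, int]
    by_immune_cell: dict[str, int]
    n_records: int
    n_rejected: int


def read_curated(
    path: str | Path, *, column_map: Mapping[str, str] | None = None
) -> tuple[list[CuratedInteraction], CuratedSummary]:
    """Read the curated-interaction CSV, validating the controlled
    vocabularies; rows with unknown interaction types are rejected with a
    logged reason."""
    colmap = {c: c for c in SCHEMAS["curated"]}
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if colmap["interaction_type"] not in df.columns:
        raise SchemaError(
            f"missing interaction_type column {colmap['interaction_type']!r}"
        )
    for req in ("gene1", "gene2", "species"):
        if colmap[req] not in df.columns:
            raise SchemaError(f"missing required column {colmap[req]!r}")
    records: list[CuratedInteraction] = []
    n_rejected = 0
    for idx, row in df.iterrows():
        def get(canon: str) -> str:
            col = colmap[canon]
            return str(row[col]).strip() if col in df.columns else ""

        itype = get("interaction_type").lower()
        if itype not in INTERACTION_TYPES:
            n_rejected += 1
            logger.info("row %d: unknown interaction_type %r, rejected", idx, itype)
            continue
        pmid_raw = get("pmid")
        try:
            pmid = int(pmid_raw) if pmid_raw else None
        except ValueError:
            n_rejected += 1
            logger.info("row %d: non-integer PMID %r, rejected", idx, pmid_raw)
            continue
        try:
            rec = CuratedInteraction(
                gene1=get("gene1"),
                gene2=get("gene2"),
                tumor_cell=get("tumor_cell"),
                immune_cell=get("immune_cell"),
                interaction_type=itype,
                species=get("species"),
                cancer_type=get("cancer_type"),
                cancer_subtype=get("cancer_subtype"),
                experiment=get("experiment"),
                description=get("description"),
                pmid=pmid,
            )
        except ValueError as exc:
            n_rejected += 1
            logger.info("row %d rejected: %s", idx, exc)
            continue
        records.append(rec)

    def count(attr: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in records:
            v = getattr(r, attr)
            if v:
                out[v] = out.get(v, 0) + 1
        return dict(sorted(out.items()))

    summary = CuratedSummary(
        by_type=count("interaction_type"),
        by_cancer=count("cancer_type"),
        by_immune_cell=count("immune_cell"),
        n_records=len(records),
        n_rejected=n_rejected,
    )
    return records, summary


def curated_to_frame(records: Sequence[CuratedInteraction]) -> pd.DataFrame:
    rows = [
        {
            **{c: getattr(r, c) for c in SCHEMAS["curated"] if c != "pmid"},
            "pmid": "" if r.pmid is None else r.pmid,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=SCHEMAS["curated"])


def write_outputs(
    results: pd.DataFrame, schema_name: str, path: str | Path
) -> Path:
    """Write a result table under a named schema with byte-stable column
    order, UTF-8 and RFC-4180 quoting.  Extra columns are dropped; missing
    schema columns raise."""
    if schema_name not in SCHEMAS:
        raise SchemaError(
            f"unknown schema {schema_name!r}; valid schemas: {sorted(SCHEMAS)}"
        )
    cols = SCHEMAS[schema_name]
    missing = [c for c in cols if c not in results.columns]
    if missing:
        raise SchemaError(f"results lack schema columns {missing} for {schema_name!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results[cols].to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Thresholds and mappings for a pipeline run.

    ``alpha`` follows the default 0.05 significance profile; the
    ``small-cohort`` profile relaxes it to 0.1 for underpowered datasets.
    ``min_samples``/``min_cells`` are the dataset admission thresholds for
    bulk and single-cell inputs respectively.
    """

    seed: int = 0
    n_perm: int = 1000
    alpha: float = 0.05
    alpha_profile: str = "default"
    min_samples: int = 6
    min_cells: int = 500
    zero_fraction_max: float = 0.30
    min_support: int = 2
    group_priority: tuple[str, ...] = FUNCTIONAL_GROUPS
    column_maps: dict = field(default_factory=dict)
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.alpha_profile == "small-cohort":
            self.alpha = 0.1
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        for name in ("n_perm", "min_samples", "min_cells", "min_support"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if sorted(self.group_priority) != sorted(FUNCTIONAL_GROUPS):
            raise ValueError("group_priority must permute the 10-group vocabulary")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "group_priority" in raw:
            raw["group_priority"] = tuple(raw["group_priority"])
        return cls(**raw)
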