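"""RepoDB-style reference sets of labelled drug-disease combinations.

A reference set lists drug-disease pairs labelled by clinical outcome:
``approved`` (on-label indications) or, for failed trials, ``terminated``,
``suspended`` or ``withdrawn``.  The cleaning pipeline mirrors the way
such sets are prepared for knowledge-graph lookup: raw drug identifiers
are normalized to their active-ingredient concept, duplicates removed,
the status classes of interest selected, and pairs with neither a direct
nor a one-intermediate path in the graph dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from kgrepurpose.graph import KnowledgeGraph, direct_path_exists, intermediate_concepts

logger = logging.getLogger(__name__)

#: Clinical outcome labels a pair may carry.
PAIR_STATUSES: tuple[str, ...] = ("approved", "terminated", "suspended", "withdrawn")


@dataclass(frozen=True)
class DrugDiseasePair:
    drug_id: str
    disease_id: str
    status: str
    drug_name: str = ""
    disease_name: str = ""
    disease_class: str | None = None  # "cancer" | "non-cancer" when known

    def __post_init__(self) -> None:
        if self.status not in PAIR_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.drug_id == self.disease_id:
            raise ValueError(f"pair with identical drug and disease id {self.drug_id!r}")

    @property
    def pair_id(self) -> str:
        return f"{self.drug_id}|{self.disease_id}"


@dataclass
class ReferenceSet:
    """An ordered list of labelled pairs."""

    pairs: list[DrugDiseasePair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def statuses(self) -> list[str]:
        return [p.status for p in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "drug_id": p.drug_id,
                    "drug_name": p.drug_name,
                    "disease_id": p.disease_id,
                    "disease_name": p.disease_name,
                    "status": p.status,
                }
                for p in self.pairs
            ],
            columns=["drug_id", "drug_name", "disease_id", "disease_name", "status"],
        )


def load_reference(path: str | Path) -> ReferenceSet:
    """Read a reference CSV: ``drug_id,drug_name,disease_id,disease_name,status``.

    Extra columns are ignored; unknown status labels are errors naming the row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"drug_id", "disease_id", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    pairs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        status = row.status.strip().lower()
        if status not in PAIR_STATUSES:
            raise ValueError(f"{path}: line {i}: unknown status {row.status!r}")
        pairs.append(
            DrugDiseasePair(
                drug_id=row.drug_id,
                disease_id=row.disease_id,
                status=status,
                drug_name=getattr(row, "drug_name", ""),
                disease_name=getattr(row, "disease_name", ""),
            )
        )
    return ReferenceSet(pairs)


def write_reference(rs: ReferenceSet, path: str | Path) -> None:
    rs.to_frame().to_csv(path, index=False)


def load_ingredient_map(path: str | Path) -> dict[str, str]:
    """Read a ``raw_id<TAB>ingredient_concept_id`` mapping table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["raw_id", "ingredient_concept_id"]:
        raise ValueError(f"{path}: expected columns raw_id, ingredient_concept_id")
    return dict(zip(df["raw_id"], df["ingredient_concept_id"]))


def load_disease_classes(path: str | Path) -> dict[str, str]:
    """Read a ``disease_id<TAB>class`` table with class in {cancer, non-cancer}."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["disease_id", "class"]:
        raise ValueError(f"{path}: expected columns disease_id, class")
    bad = set(df["class"]) - {"cancer", "non-cancer"}
    if bad:
        raise ValueError(f"{path}: unknown disease classes {sorted(bad)}")
    return dict(zip(df["disease_id"], df["class"]))


# ---------------------------------------------------------------------------
# cleaning pipeline


def map_active_ingredients(rs: ReferenceSet, mapping: dict[str, str]) -> ReferenceSet:
    """Replace raw drug identifiers by their active-ingredient concept.

    Distinct products sharing an ingredient collapse to the same drug
    concept and become duplicates, which ``deduplicate`` then resolves.
    Every drug id must be mapped; offenders are reported together.
    """
    unmapped = sorted({p.drug_id for p in rs.pairs if p.drug_id not in mapping})
    if unmapped:
        raise KeyError(f"unmapped drug identifiers: {unmapped}")
    return ReferenceSet([replace(p, drug_id=mapping[p.drug_id]) for p in rs.pairs])


def deduplicate(rs: ReferenceSet) -> ReferenceSet:
    """Drop repeated (drug, disease, status) entries, keeping first occurrence.

    The same combination under both an approved and a terminated label is
    two distinct instances and both are kept.
    """
    seen: set[tuple[str, str, str]] = set()
    out = []
    for p in rs.pairs:
        key = (p.drug_id, p.disease_id, p.status)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return ReferenceSet(out)


def select_statuses(rs: ReferenceSet, keep: set[str]) -> ReferenceSet:
    """Keep only pairs whose status is in ``keep`` (order preserved)."""
    if not keep:
        raise ValueError("keep set must be non-empty")
    unknown = set(keep) - set(PAIR_STATUSES)
    if unknown:
        raise ValueError(f"unknown statuses {sorted(unknown)}")
    return ReferenceSet([p for p in rs.pairs if p.status in keep])


def filter_connected(rs: ReferenceSet, g: KnowledgeGraph) -> ReferenceSet:
    """Keep pairs with a direct path or at least one intermediate concept.

    Pairs whose drug or disease concept is absent from the graph cannot be
    featurized and are dropped; the count is logged.
    """
    kept, absent, unconnected = [], 0, 0
    for p in rs.pairs:
        if p.drug_id not in g or p.disease_id not in g:
            absent += 1
            continue
        if direct_path_exists(g, p.drug_id, p.disease_id) or intermediate_concepts(
            g, p.drug_id, p.disease_id
        ):
            kept.append(p)
        else:
            unconnected += 1
    logger.info(
        "filter_connected: kept %d of %d pairs (%d with concepts absent from graph, "
        "%d without direct or indirect path)",
        len(kept), len(rs), absent, unconnected,
    )
    return ReferenceSet(kept)


def attach_disease_classes(rs: ReferenceSet, classes: dict[str, str]) -> ReferenceSet:
    """Label every pair with its disease class (cancer / non-cancer)."""
    missing = sorted({p.disease_id for p in rs.pairs if p.disease_id not in classes})
    if missing:
        raise KeyError(f"diseases without class label: {missing}")
    return ReferenceSet([replace(p, disease_class=classes[p.disease_id]) for p in rs.pairs])


def partition_by_disease_class(rs: ReferenceSet) -> tuple[ReferenceSet, ReferenceSet]:
    """Split into (cancer, non-cancer) subsets; every pair must be labelled."""
    unlabelled = [p.pair_id for p in rs.pairs if p.disease_class is None]
    if unlabelled:
        raise ValueError(f"pairs without disease_class: {unlabelled[:5]}...")
    cancer = ReferenceSet([p for p in rs.pairs if p.disease_class == "cancer"])
    non_cancer = ReferenceSet([p for p in rs.pairs if p.disease_class == "non-cancer"])
    return cancer, non_cancer


def subsample_to_ratio(
    rs: ReferenceSet, positive_to_negative: float, seed: int
) -> ReferenceSet:
    """Downsample one class to hit a target approved:terminated ratio.

    Exactly one class is downsampled uniformly without replacement (seeded);
    the other is untouched.  The achieved ratio is within one pair of the
    target.  Original pair order is preserved.
    """
    if positive_to_negative <= 0:
        raise ValueError("ratio must be positive")
    pos_idx = [i for i, p in enumerate(rs.pairs) if p.status == "approved"]
    neg_idx = [i for i, p in enumerate(rs.pairs) if p.status == "terminated"]
    n_pos, n_neg = len(pos_idx), len(neg_idx)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both approved and terminated pairs required")
    rng = np.random.default_rng(seed)
    current = n_pos / n_neg
    if current > positive_to_negative:
        # too many positives
        target = int(round(positive_to_negative * n_neg))
        if target < 1:
            raise ValueError("target ratio unreachable by downsampling one class")
        keep = set(rng.choice(pos_idx, size=target, replace=False).tolist()) | set(neg_idx)
    else:
        target = int(round(n_pos / positive_to_negative))
        if target < 1:
            raise ValueError("target ratio unreachable by downsampling one class")
        keep = set(pos_idx) | set(rng.choice(neg_idx, size=target, replace=False).tolist())
    return ReferenceSet([p for i, p in enumerate(rs.pairs) if i in keep])


# ---------------------------------------------------------------------------
# summaries


@dataclass
class SetSummary:
    """Per-status counts of drugs, diseases, pairs and direct paths."""

    per_status: dict[str, dict[str, int]]
    overall: dict[str, int]
    direct_path_pct: dict[str, int | None]

    def to_dict(self) -> dict:
        return {
            "per_status": self.per_status,
            "overall": self.overall,
            "direct_path_pct": self.direct_path_pct,
        }


def summarize(rs: ReferenceSet, g: KnowledgeGraph) -> SetSummary:
    """Count unique drugs, diseases, pairs and direct paths per status.

    Direct-path percentages are rounded to the nearest integer; undefined
    (None) for a status with no pairs.  Pairs with concepts absent from the
    graph count as having no direct path.
    """
    def block(pairs: list[DrugDiseasePair]) -> dict[str, int]:
        direct = sum(
            1
            for p in pairs
            if p.drug_id in g
            and p.disease_id in g
            and direct_path_exists(g, p.drug_id, p.disease_id)
        )
        return {
            "n_drugs": len({p.drug_id for p in pairs}),
            "n_diseases": len({p.disease_id for p in pairs}),
            "n_pairs": len(pairs),
            "n_direct_paths": direct,
        }

    statuses = sorted({p.status for p in rs.pairs})
    per_status = {s: block([p for p in rs.pairs if p.status == s]) for s in statuses}
    overall = block(rs.pairs)
    pct: dict[str, int | None] = {}
    for s, b in {**per_status, "all": overall}.items():
        pct[s] = int(round(100 * b["n_direct_paths"] / b["n_pairs"])) if b["n_pairs"] else None
    return SetSummary(per_status=per_status, overall=overall, direct_path_pct=pct)
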