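"""Feature construction for drug-disease pairs.

Each pair is represented by one binary feature (is there any single triple
joining drug and disease?) and integer frequency features over the
semantic annotations of its intermediate concepts: each unique
intermediate adds 1 to the feature of its single semantic group and 1 to
the feature of each of its semantic types.  Since a concept has exactly
one group, the group counts always sum to the number of intermediates,
while the type counts can exceed it for multi-typed concepts.

Feature columns are named ``group:<label>`` and ``type:<label>`` so the
two vocabularies cannot collide; ``direct_path`` is always the first
column.  The schema (ordered names plus whether it was built from the
observed pairs or from a full vocabulary) is part of any trained model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from kgrepurpose.graph import KnowledgeGraph, direct_path_exists, intermediate_concepts
from kgrepurpose.reference import DrugDiseasePair, ReferenceSet
from kgrepurpose.vocab import SemanticVocabulary

logger = logging.getLogger(__name__)

DIRECT = "direct_path"
GROUP_PREFIX = "group:"
TYPE_PREFIX = "type:"


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names: direct_path, then groups, then types."""

    names: tuple[str, ...]
    provenance: str  # "observed" | "full-vocabulary"

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not self.names or self.names[0] != DIRECT:
            raise ValueError(f"first feature must be {DIRECT!r}")

    @classmethod
    def from_labels(
        cls, groups: set[str], types: set[str], provenance: str
    ) -> "FeatureSchema":
        names = (
            (DIRECT,)
            + tuple(GROUP_PREFIX + g for g in sorted(groups))
            + tuple(TYPE_PREFIX + t for t in sorted(types))
        )
        return cls(names=names, provenance=provenance)

    @property
    def group_features(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n.startswith(GROUP_PREFIX))

    @property
    def type_features(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n.startswith(TYPE_PREFIX))

    def __len__(self) -> int:
        return len(self.names)

    def to_dict(self) -> dict:
        return {"names": list(self.names), "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(names=tuple(d["names"]), provenance=d["provenance"])


@dataclass
class FeatureVector:
    """Featurization of a single pair, before schema alignment."""

    direct_path: int
    group_counts: dict[str, int]
    type_counts: dict[str, int]

    def to_row(self, schema: FeatureSchema) -> np.ndarray:
        """Align to a schema; labels absent from the schema are dropped
        with a warning (they can arise when scoring novel candidates with
        a trained model's schema)."""
        row = np.zeros(len(schema), dtype=np.int64)
        index = {n: i for i, n in enumerate(schema.names)}
        row[index[DIRECT]] = self.direct_path
        dropped = []
        for label, count in self.group_counts.items():
            key = GROUP_PREFIX + label
            if key in index:
                row[index[key]] = count
            else:
                dropped.append(key)
        for label, count in self.type_counts.items():
            key = TYPE_PREFIX + label
            if key in index:
                row[index[key]] = count
            else:
                dropped.append(key)
        if dropped:
            logger.warning("features outside schema dropped: %s", sorted(dropped))
        return row


@dataclass
class FeatureMatrix:
    """Rows = pairs in input order, columns = schema order, integer values."""

    schema: FeatureSchema
    values: np.ndarray
    pair_ids: list[str]
    labels: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64).reshape(
            len(self.pair_ids), len(self.schema)
        )
        if not self.labels:
            self.labels = [None] * len(self.pair_ids)
        if len(self.labels) != len(self.pair_ids):
            raise ValueError("labels misaligned with rows")

    @property
    def n_rows(self) -> int:
        return len(self.pair_ids)

    def has_labels(self) -> bool:
        return all(l is not None for l in self.labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.schema.names))
        df.insert(0, "label", ["" if l is None else l for l in self.labels])
        df.insert(0, "pair_id", self.pair_ids)
        return df

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        idx = np.flatnonzero(mask)
        return FeatureMatrix(
            schema=self.schema,
            values=self.values[idx],
            pair_ids=[self.pair_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# construction


def build_schema(
    g: KnowledgeGraph,
    rs: ReferenceSet,
    mode: str = "observed",
    vocab: SemanticVocabulary | None = None,
) -> FeatureSchema:
    """Build the feature schema.

    ``observed``: features for exactly the groups and types occurring among
    the intermediates of the reference pairs (the set should already be
    connectivity-filtered).  ``full``: one feature per vocabulary entry,
    observed or not.  Order is deterministic (sorted).
    """
    if mode == "full":
        if vocab is None:
            raise ValueError("full mode requires a vocabulary")
        return FeatureSchema.from_labels(
            set(vocab.group_names), set(vocab.type_names), "full-vocabulary"
        )
    if mode != "observed":
        raise ValueError(f"unknown schema mode {mode!r}")
    groups: set[str] = set()
    types: set[str] = set()
    for p in rs.pairs:
        for cid in intermediate_concepts(g, p.drug_id, p.disease_id):
            c = g.concepts[cid]
            groups.add(c.semantic_group)
            types.update(c.semantic_types)
    if not groups:
        raise ValueError("no intermediate concepts observed; cannot build schema")
    return FeatureSchema.from_labels(groups, types, "observed")


def featurize_pair(
    g: KnowledgeGraph, pair: DrugDiseasePair, schema: FeatureSchema | None = None
) -> FeatureVector | np.ndarray:
    """Featurize one pair; returns an aligned row when a schema is given.

    Each unique intermediate concept contributes 1 to its semantic group
    and 1 to each of its semantic types, regardless of how many triples
    connect it to the pair.
    """
    direct = int(direct_path_exists(g, pair.drug_id, pair.disease_id))
    group_counts: dict[str, int] = {}
    type_counts: dict[str, int] = {}
    for cid in intermediate_concepts(g, pair.drug_id, pair.disease_id):
        c = g.concepts[cid]
        group_counts[c.semantic_group] = group_counts.get(c.semantic_group, 0) + 1
        for t in c.semantic_types:
            type_counts[t] = type_counts.get(t, 0) + 1
    vec = FeatureVector(direct_path=direct, group_counts=group_counts, type_counts=type_counts)
    if schema is None:
        return vec
    return vec.to_row(schema)


def featurize_all(
    g: KnowledgeGraph, rs: ReferenceSet, schema: FeatureSchema
) -> FeatureMatrix:
    """Row-stack featurize_pair over a reference set, labels attached."""
    rows = np.zeros((len(rs), len(schema)), dtype=np.int64)
    for i, p in enumerate(rs.pairs):
        try:
            rows[i] = featurize_pair(g, p, schema)
        except KeyError as exc:
            raise KeyError(f"row {i} ({p.pair_id}): {exc}") from exc
    return FeatureMatrix(
        schema=schema,
        values=rows,
        pair_ids=[p.pair_id for p in rs.pairs],
        labels=[p.status for p in rs.pairs],
    )


# ---------------------------------------------------------------------------
# serialization


def _sidecar(path: str | Path) -> Path:
    return Path(str(path) + ".schema.json")


def write_matrix(m: FeatureMatrix, path: str | Path) -> None:
    """TSV (pair_id, label, then schema columns) plus a schema sidecar JSON."""
    m.to_frame().to_csv(path, sep="\t", index=False)
    with open(_sidecar(path), "w") as fh:
        json.dump(m.schema.to_dict(), fh, indent=1)


def read_matrix(path: str | Path, schema: FeatureSchema | None = None) -> FeatureMatrix:
    """Inverse of write_matrix; verifies columns against the stored (or a
    caller-supplied) schema."""
    with open(_sidecar(path)) as fh:
        stored = FeatureSchema.from_dict(json.load(fh))
    if schema is not None and schema.names != stored.names:
        raise ValueError("matrix schema does not match the expected schema")
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "label": str}, keep_default_na=False)
    if tuple(df.columns[2:]) != stored.names:
        raise ValueError("matrix columns do not match schema sidecar")
    labels = [None if l == "" else l for l in df["label"]]
    return FeatureMatrix(
        schema=stored,
        values=df[list(stored.names)].to_numpy(dtype=np.int64),
        pair_ids=df["pair_id"].tolist(),
        labels=labels,
    )
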