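"""UMLS-style semantic vocabularies.

Every concept in the knowledge graph carries one or more *semantic types*
(fine-grained categories such as "Enzyme" or "Sign or Symptom") and exactly
one *semantic group* (one of 15 coarse categories such as "Chemicals &
Drugs").  The full UMLS inventory has 137 types; because the UMLS files are
licensed, the package bundles a miniature vocabulary (the 15 real group
names plus a 20-type subset) sufficient for the method, and accepts a
user-supplied type->group table for the full inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

#: The 15 UMLS semantic groups (Bodenreider & McCray's coarse partition).
UMLS_SEMANTIC_GROUPS: tuple[str, ...] = (
    "Activities & Behaviors",
    "Anatomy",
    "Chemicals & Drugs",
    "Concepts & Ideas",
    "Devices",
    "Disorders",
    "Genes & Molecular Sequences",
    "Geographic Areas",
    "Living Beings",
    "Objects",
    "Occupations",
    "Organizations",
    "Phenomena",
    "Physiology",
    "Procedures",
)


@dataclass(frozen=True)
class SemanticVocabulary:
    """Label sets for semantic types and groups.

    ``type_to_group`` is advisory: it records the canonical group of each
    type and drives consistent type/group assignment in the synthetic
    generator, but concepts declare their own single group (a concept with
    several types may straddle groups, so the map cannot be enforced per
    concept).
    """

    type_names: frozenset[str]
    group_names: frozenset[str]
    type_to_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.type_names:
            raise ValueError("vocabulary must define at least one semantic type")
        if not self.group_names:
            raise ValueError("vocabulary must define at least one semantic group")
        bad = {g for g in self.type_to_group.values() if g not in self.group_names}
        if bad:
            raise ValueError(f"type_to_group targets unknown groups: {sorted(bad)}")

    def groups_with_types(self) -> dict[str, list[str]]:
        """Group -> sorted list of types canonically mapped to it."""
        out: dict[str, list[str]] = {}
        for t, g in self.type_to_group.items():
            out.setdefault(g, []).append(t)
        return {g: sorted(ts) for g, ts in out.items()}


def load_vocabulary(path: str | Path, extra_groups: tuple[str, ...] = ()) -> SemanticVocabulary:
    """Load a ``type_name<TAB>group_name`` table (UMLS SemGroups-style).

    Group names appearing in the table are always included; ``extra_groups``
    adds groups that have no mapped type in the table.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"type_name", "group_name"}
    if not required.issubset(df.columns):
        raise ValueError(f"vocabulary table must have columns {sorted(required)}")
    if df["type_name"].duplicated().any():
        dupes = df.loc[df["type_name"].duplicated(), "type_name"].tolist()
        raise ValueError(f"duplicate semantic types in vocabulary: {dupes}")
    mapping = dict(zip(df["type_name"], df["group_name"]))
    return SemanticVocabulary(
        type_names=frozenset(mapping),
        group_names=frozenset(mapping.values()) | frozenset(extra_groups),
        type_to_group=mapping,
    )


def mini_vocabulary() -> SemanticVocabulary:
    """The bundled miniature vocabulary: all 15 groups, 20 common types."""
    ref = resources.files("kgrepurpose.data").joinpath("mini_vocab.tsv")
    with resources.as_file(ref) as path:
        return load_vocabulary(path, extra_groups=UMLS_SEMANTIC_GROUPS)
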