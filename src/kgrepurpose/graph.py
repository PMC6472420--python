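"""Typed knowledge-graph model and path queries.

The graph is built from subject-predicate-object triples over typed
biomedical concepts.  The method's features need exactly three queries:
whether a drug and a disease are joined by a single edge (a *direct path*),
the set of concepts adjacent to both (the *intermediate concepts* of the
two-edge indirect paths), and a concept's whole-graph degree.  Path queries
treat edges as undirected by default; stored edges keep their direction,
predicate, provenance source and evidence count for explanation output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from kgrepurpose.vocab import SemanticVocabulary


@dataclass(frozen=True)
class Concept:
    """A graph vertex: one or more semantic types, exactly one group."""

    id: str
    name: str
    semantic_types: frozenset[str]
    semantic_group: str

    def __post_init__(self) -> None:
        if not self.semantic_types:
            raise ValueError(f"concept {self.id!r} has no semantic type")
        if not self.semantic_group:
            raise ValueError(f"concept {self.id!r} has no semantic group")


@dataclass(frozen=True)
class Edge:
    """A stored triple with provenance.

    ``evidence_count`` is the number of supporting records (database
    entries or publications) behind the triple.
    """

    subject: str
    predicate: str
    object: str
    source: str = ""
    evidence_count: int = 1

    def __post_init__(self) -> None:
        if self.subject == self.object:
            raise ValueError(f"self-loop on {self.subject!r}")
        if self.evidence_count < 0:
            raise ValueError("evidence_count must be non-negative")


class KnowledgeGraph:
    """Concept index plus edges with a direction-collapsed adjacency.

    Multiple triples between the same pair of concepts collapse to a single
    adjacency entry; the underlying edges are all retained.
    """

    def __init__(
        self,
        concepts: dict[str, Concept],
        edges: list[Edge],
        directed: bool = False,
    ) -> None:
        self.concepts = concepts
        self.edges = edges
        self.directed = directed
        self._succ: dict[str, set[str]] = {cid: set() for cid in concepts}
        self._pred: dict[str, set[str]] = {cid: set() for cid in concepts}
        for e in edges:
            for endpoint in (e.subject, e.object):
                if endpoint not in concepts:
                    raise KeyError(f"edge endpoint {endpoint!r} not in concept table")
            self._succ[e.subject].add(e.object)
            self._pred[e.object].add(e.subject)

    @classmethod
    def from_concepts_and_edges(
        cls, concepts: list[Concept], edges: list[Edge], directed: bool = False
    ) -> "KnowledgeGraph":
        index: dict[str, Concept] = {}
        for c in concepts:
            if c.id in index:
                raise ValueError(f"duplicate concept id {c.id!r}")
            index[c.id] = c
        return cls(index, list(edges), directed=directed)

    def _require(self, cid: str) -> None:
        if cid not in self.concepts:
            raise KeyError(f"unknown concept id {cid!r}")

    def neighbors(self, cid: str) -> set[str]:
        """Distinct neighbors of ``cid`` (out-neighbors only if directed)."""
        self._require(cid)
        if self.directed:
            return set(self._succ[cid])
        return self._succ[cid] | self._pred[cid]

    def in_neighbors(self, cid: str) -> set[str]:
        self._require(cid)
        if self.directed:
            return set(self._pred[cid])
        return self._succ[cid] | self._pred[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)


@dataclass
class ExplanationSubgraph:
    """The pair, its intermediate concepts, and all edges among them."""

    focus_pair: tuple[str, str]
    nodes: set[str]
    edges: list[Edge] = field(default_factory=list)


# ---------------------------------------------------------------------------
# loading / writing


def _parse_types(raw: str) -> frozenset[str]:
    return frozenset(t.strip() for t in str(raw).split("|") if t.strip())


def load_graph(
    concepts_path: str | Path,
    triples_path: str | Path,
    vocab: SemanticVocabulary | None = None,
    directed: bool = False,
) -> KnowledgeGraph:
    """Load a graph from the concept and triple TSV tables.

    Concept rows are ``id<TAB>name<TAB>types`` (pipe-separated)
    ``<TAB>group``; triples are ``subject<TAB>predicate<TAB>object<TAB>
    source<TAB>evidence_count``.  When a vocabulary is given, semantic
    labels outside it are load-time errors, as are concepts with zero
    types or no group, duplicate ids, self-loops and dangling endpoints.
    """
    cdf = pd.read_csv(concepts_path, sep="\t", dtype=str, keep_default_na=False)
    required = ["id", "name", "semantic_types", "semantic_group"]
    if list(cdf.columns[:4]) != required:
        raise ValueError(f"concept table must start with columns {required}")
    concepts: list[Concept] = []
    for i, row in enumerate(cdf.itertuples(index=False), start=2):
        types = _parse_types(row.semantic_types)
        if not types:
            raise ValueError(f"{concepts_path}: line {i}: concept {row.id!r} has empty semantic_types")
        if not row.semantic_group:
            raise ValueError(f"{concepts_path}: line {i}: concept {row.id!r} has empty semantic_group")
        if vocab is not None:
            unknown = types - vocab.type_names
            if unknown:
                raise ValueError(
                    f"{concepts_path}: line {i}: unknown semantic types {sorted(unknown)}"
                )
            if row.semantic_group not in vocab.group_names:
                raise ValueError(
                    f"{concepts_path}: line {i}: unknown semantic group {row.semantic_group!r}"
                )
        concepts.append(
            Concept(
                id=row.id,
                name=row.name,
                semantic_types=types,
                semantic_group=row.semantic_group,
            )
        )

    tdf = pd.read_csv(triples_path, sep="\t", dtype=str, keep_default_na=False)
    trequired = ["subject", "predicate", "object", "source", "evidence_count"]
    if list(tdf.columns[:5]) != trequired:
        raise ValueError(f"triple table must start with columns {trequired}")
    edges: list[Edge] = []
    for i, row in enumerate(tdf.itertuples(index=False), start=2):
        try:
            ev = int(row.evidence_count)
        except ValueError as exc:
            raise ValueError(
                f"{triples_path}: line {i}: non-integer evidence_count {row.evidence_count!r}"
            ) from exc
        try:
            edges.append(
                Edge(
                    subject=row.subject,
                    predicate=row.predicate,
                    object=row.object,
                    source=row.source,
                    evidence_count=ev,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{triples_path}: line {i}: {exc}") from exc

    return KnowledgeGraph.from_concepts_and_edges(concepts, edges, directed=directed)


def write_graph(
    g: KnowledgeGraph, concepts_path: str | Path, triples_path: str | Path
) -> None:
    """Write the graph back to the two TSV tables (inverse of load_graph)."""
    crows = [
        {
            "id": c.id,
            "name": c.name,
            "semantic_types": "|".join(sorted(c.semantic_types)),
            "semantic_group": c.semantic_group,
        }
        for c in g.concepts.values()
    ]
    pd.DataFrame(crows, columns=["id", "name", "semantic_types", "semantic_group"]).to_csv(
        concepts_path, sep="\t", index=False
    )
    trows = [
        {
            "subject": e.subject,
            "predicate": e.predicate,
            "object": e.object,
            "source": e.source,
            "evidence_count": e.evidence_count,
        }
        for e in g.edges
    ]
    pd.DataFrame(
        trows, columns=["subject", "predicate", "object", "source", "evidence_count"]
    ).to_csv(triples_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# path queries


def direct_path_exists(g: KnowledgeGraph, a: str, b: str) -> bool:
    """True iff at least one triple joins ``a`` and ``b``, any predicate."""
    g._require(b)
    return b in g.neighbors(a)


def intermediate_concepts(g: KnowledgeGraph, a: str, b: str) -> set[str]:
    """Concepts adjacent to both ``a`` and ``b`` (middle vertices of the
    two-edge indirect paths).  Each concept counts once regardless of how
    many predicates or directions connect it."""
    if a == b:
        raise ValueError("intermediate_concepts requires two distinct concepts")
    return (g.neighbors(a) & g.in_neighbors(b)) - {a, b}


def degree(g: KnowledgeGraph, a: str) -> int:
    """Number of distinct concepts ``a`` is connected to in the whole graph."""
    return len(g.neighbors(a) | g.in_neighbors(a))


def extract_explanation_subgraph(g: KnowledgeGraph, a: str, b: str) -> ExplanationSubgraph:
    """Subgraph over the pair and its intermediates, evidence retained.

    Contains every stored edge among the node set, so downstream rendering
    can weight arrows by the amount of underlying evidence.
    """
    g._require(a)
    g._require(b)
    nodes = {a, b} | (intermediate_concepts(g, a, b) if a != b else set())
    edges = [e for e in g.edges if e.subject in nodes and e.object in nodes]
    return ExplanationSubgraph(focus_pair=(a, b), nodes=nodes, edges=edges)


def explanation_to_graphml(
    g: KnowledgeGraph, sub: ExplanationSubgraph, path: str | Path
) -> None:
    """Export an explanation subgraph as GraphML.

    Parallel triples between a pair of concepts collapse to one edge whose
    ``evidence_count`` is the sum over the underlying triples; nodes carry
    their ``semantic_group``.
    """
    out = nx.Graph()
    for cid in sorted(sub.nodes):
        c = g.concepts[cid]
        out.add_node(cid, name=c.name, semantic_group=c.semantic_group)
    for e in sub.edges:
        u, v = sorted((e.subject, e.object))
        if out.has_edge(u, v):
            out[u][v]["evidence_count"] += e.evidence_count
        else:
            out.add_edge(u, v, evidence_count=e.evidence_count)
    nx.write_graphml(out, path)
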