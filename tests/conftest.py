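"""Shared fixtures: toy graphs, random-graph builders, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from kgrepurpose.graph import Concept, Edge, KnowledgeGraph
from kgrepurpose.reference import DrugDiseasePair, ReferenceSet
from kgrepurpose.vocab import mini_vocabulary

GROUPS_WITH_TYPES = mini_vocabulary().groups_with_types()


def make_concept(cid, types, group, name=None):
    return Concept(
        id=cid, name=name or cid, semantic_types=frozenset(types), semantic_group=group
    )


@pytest.fixture(scope="session")
def vocab():
    return mini_vocabulary()


@pytest.fixture
def tg1():
    """Toy graph: drug D, disease S, intermediates C1/C2, spur C3,
    isolated C4.

    Edges: D-C1, C1-S, D-C2, C2-S, D-S, D-C3.
    """
    concepts = [
        make_concept("D", ["Pharmacologic Substance"], "Chemicals & Drugs"),
        make_concept("S", ["Disease or Syndrome"], "Disorders"),
        make_concept("C1", ["Enzyme"], "Chemicals & Drugs"),
        make_concept("C2", ["Sign or Symptom"], "Disorders"),
        make_concept("C3", ["Cell"], "Anatomy"),
        make_concept("C4", ["Tissue"], "Anatomy"),
    ]
    edges = [
        Edge("D", "interacts_with", "C1", "src", 2),
        Edge("C1", "associated_with", "S", "src", 3),
        Edge("D", "interacts_with", "C2", "src", 1),
        Edge("C2", "associated_with", "S", "src", 1),
        Edge("D", "treats", "S", "src", 5),
        Edge("D", "interacts_with", "C3", "src", 1),
    ]
    return KnowledgeGraph.from_concepts_and_edges(concepts, edges)


@pytest.fixture
def fig2_graph():
    """The worked four-intermediate configuration: IC1 Pharmacologic
    Substance (Chemicals & Drugs), IC2 & IC4 Sign or Symptom (Phenomena),
    IC3 Enzyme (Chemicals & Drugs), all adjacent to both drug and disease."""
    concepts = [
        make_concept("DRUG", ["Pharmacologic Substance"], "Chemicals & Drugs"),
        make_concept("DIS", ["Disease or Syndrome"], "Disorders"),
        make_concept("IC1", ["Pharmacologic Substance"], "Chemicals & Drugs"),
        make_concept("IC2", ["Sign or Symptom"], "Phenomena"),
        make_concept("IC3", ["Enzyme"], "Chemicals & Drugs"),
        make_concept("IC4", ["Sign or Symptom"], "Phenomena"),
    ]
    edges = [Edge("DRUG", "r", ic, "src", 1) for ic in ("IC1", "IC2", "IC3", "IC4")]
    edges += [Edge(ic, "r", "DIS", "src", 1) for ic in ("IC1", "IC2", "IC3", "IC4")]
    edges += [Edge("DRUG", "treats", "DIS", "src", 1)]
    return KnowledgeGraph.from_concepts_and_edges(concepts, edges)


def random_graph(rng: np.random.Generator, n_concepts=20, n_edges=60) -> KnowledgeGraph:
    """A random typed multigraph (possibly with parallel edges)."""
    groups = sorted(GROUPS_WITH_TYPES)
    concepts = []
    for i in range(n_concepts):
        g = groups[rng.integers(len(groups))]
        types = list(rng.choice(GROUPS_WITH_TYPES[g],
                                size=min(1 + rng.integers(2), len(GROUPS_WITH_TYPES[g])),
                                replace=False))
        concepts.append(make_concept(f"N{i}", types, g))
    edges = []
    while len(edges) < n_edges:
        u, v = rng.integers(n_concepts, size=2)
        if u == v:
            continue
        edges.append(Edge(f"N{u}", "rel", f"N{v}", "src", int(rng.integers(1, 5))))
    return KnowledgeGraph.from_concepts_and_edges(concepts, edges)


# --------------------------------------------------------------------------
# brute-force oracles (independent of the adjacency-index implementation)


def oracle_direct(g: KnowledgeGraph, a: str, b: str) -> bool:
    return any(
        (e.subject == a and e.object == b) or (e.subject == b and e.object == a)
        for e in g.edges
    )


def oracle_intermediates(g: KnowledgeGraph, a: str, b: str) -> set[str]:
    """Enumerate all ordered pairs of edges forming a two-edge path a-c-b."""
    out = set()
    for e1 in g.edges:
        for e2 in g.edges:
            ends1 = {e1.subject, e1.object}
            ends2 = {e2.subject, e2.object}
            if a not in ends1 or b not in ends2:
                continue
            shared = (ends1 - {a}) & (ends2 - {b})
            out |= shared - {a, b}
    return out


def oracle_auc(scores, labels) -> float:
    """Mann-Whitney pair counting, ties half a point."""
    pos = [s for s, l in zip(scores, labels) if l == "approved"]
    neg = [s for s, l in zip(scores, labels) if l != "approved"]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def oracle_tau_b(x, y) -> float:
    """O(n^2) concordant/discordant enumeration with tie correction."""
    n = len(x)
    conc = disc = tied_x = tied_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tied_x += 1
                tied_y += 1
            elif dx == 0:
                tied_x += 1
            elif dy == 0:
                tied_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt((n0 - tied_x) * (n0 - tied_y))
    return (conc - disc) / denom


def toy_reference(rows) -> ReferenceSet:
    """Build a reference set from (drug, disease, status[, disease_class])."""
    pairs = []
    for row in rows:
        drug, disease, status = row[:3]
        cls = row[3] if len(row) > 3 else None
        pairs.append(
            DrugDiseasePair(drug_id=drug, disease_id=disease, status=status,
                            disease_class=cls)
        )
    return ReferenceSet(pairs)
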