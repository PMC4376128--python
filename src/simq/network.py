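"""Semantic dependency network: type frequencies and type-pair edge weights.

Aggregating one topic category's questions gives an overview of what the
category is about: nodes are semantic types weighted by how often entities of
that type occur, edges are unordered type pairs weighted by how often a
dependency relation links entities of the two types.  Exports to edge-list
TSV or GraphML for downstream graph tooling; no layout is attempted here.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .dependency import SemanticRelation
from .errors import SimQError
from .lexicon import AnnotatedQuestion

logger = logging.getLogger(__name__)

ALL_CATEGORIES = "all"


@dataclass
class SemanticNetwork:
    category: str
    n_questions: int = 0
    nodes: Counter = field(default_factory=Counter)
    # keys are alphabetically ordered (type_a, type_b) tuples
    edges: Counter = field(default_factory=Counter)

    def is_empty(self) -> bool:
        return not self.nodes


def _edge_key(type_a: str, type_b: str) -> tuple[str, str]:
    return (type_a, type_b) if type_a <= type_b else (type_b, type_a)


def build_network(
    annotated: Iterable[tuple[AnnotatedQuestion, list[SemanticRelation]]],
    category: str = ALL_CATEGORIES,
) -> SemanticNetwork:
    """Tally entity occurrences (nodes) and relation type pairs (edges).

    Node counts are per occurrence, not per distinct question.  Questions
    outside the requested category are ignored; ``category="all"`` keeps
    everything.
    """
    net = SemanticNetwork(category=category)
    for aq, relations in annotated:
        if category != ALL_CATEGORIES and aq.category != category:
            continue
        net.n_questions += 1
        for chunk in aq.entity_chunks():
            net.nodes[chunk.semantic_type] += 1
        for rel in relations:
            net.edges[_edge_key(rel.governor_type, rel.dependent_type)] += 1
    if net.is_empty():
        logger.warning("category %r matched no annotated entities; network is empty", category)
    return net


def export_network(net: SemanticNetwork, path: str | Path, format: str = "tsv") -> None:
    """Write the network; ``tsv`` (edge list) or ``graphml``, sorted rows."""
    path = Path(path)
    if format == "tsv":
        lines = ["type_a\ttype_b\tweight"]
        for (a, b), w in sorted(net.edges.items()):
            lines.append(f"{a}\t{b}\t{w}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "graphml":
        if net.is_empty():
            raise SimQError("refusing to write GraphML for an empty network")
        graph = nx.Graph(category=net.category, n_questions=net.n_questions)
        for node in sorted(net.nodes):
            graph.add_node(node, frequency=net.nodes[node])
        for (a, b), w in sorted(net.edges.items()):
            graph.add_edge(a, b, weight=w)
        nx.write_graphml(graph, path)
    else:
        raise SimQError(f"unknown network export format: {format!r}")


def read_network_tsv(path: str | Path) -> Counter:
    """Read an edge-list TSV back into an edge Counter."""
    edges: Counter = Counter()
    lines = Path(path).read_text("utf-8").splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        a, b, w = line.split("\t")
        edges[_edge_key(a, b)] = int(w)
    return edges


def read_network_graphml(path: str | Path) -> SemanticNetwork:
    """Read a GraphML export back into a SemanticNetwork (inverse of export)."""
    graph = nx.read_graphml(path)
    net = SemanticNetwork(
        category=graph.graph.get("category", ALL_CATEGORIES),
        n_questions=int(graph.graph.get("n_questions", 0)),
    )
    for node, data in graph.nodes(data=True):
        net.nodes[node] = int(data["frequency"])
    for a, b, data in graph.edges(data=True):
        net.edges[_edge_key(a, b)] = int(data["weight"])
    return net
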