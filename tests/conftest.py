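"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own traversal code:
reachability is computed by boolean matrix closure, distances by exhaustive
breadth-first search over explicit adjacency dictionaries, and pattern
containment by string matching on space-joined tokens.  They exist to check
the package's graph primitives and case polarities from first principles.
"""

from __future__ import annotations

import logging
from collections import deque

import numpy as np
import pytest

from ontoaudit import figure1_ontology
from ontoaudit.model import OntologyGraph

logging.disable(logging.WARNING)

FIG1 = "http://example.org/fig1#"


@pytest.fixture(scope="session")
def fig1() -> OntologyGraph:
    return figure1_ontology()


def f1(name: str) -> str:
    """Figure-1 IRI shorthand."""
    return FIG1 + name


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------


def closure_matrix(nodes: list[str], edges) -> np.ndarray:
    """Reflexive-transitive closure by repeated boolean matrix products."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    adj = np.zeros((n, n), dtype=bool)
    for s, t in edges:
        adj[idx[s], idx[t]] = True
    prev = None
    while prev is None or not np.array_equal(reach, prev):
        prev = reach.copy()
        reach = reach | (reach @ adj)
    return reach


def oracle_descendants(graph: OntologyGraph, c: str) -> set[str]:
    nodes = sorted(graph.nodes)
    reach = closure_matrix(nodes, graph.subclass_edges)
    idx = {n: i for i, n in enumerate(nodes)}
    return {n for n in nodes if n != c and reach[idx[n], idx[c]]}


def oracle_related(graph: OntologyGraph, a: str, b: str) -> bool:
    nodes = sorted(graph.nodes)
    reach = closure_matrix(nodes, graph.semantic_edges.keys())
    idx = {n: i for i, n in enumerate(nodes)}
    return bool(reach[idx[a], idx[b]] or reach[idx[b], idx[a]])


def oracle_distance(graph: OntologyGraph, a: str, b: str) -> int | None:
    """All-pairs-style BFS over the undirected is-a adjacency."""
    adj: dict[str, set[str]] = {}
    for s, t in graph.subclass_edges:
        adj.setdefault(s, set()).add(t)
        adj.setdefault(t, set()).add(s)
    seen = {a: 0}
    queue = deque([a])
    while queue:
        node = queue.popleft()
        if node == b:
            return seen[node]
        for nxt in adj.get(node, ()):
            if nxt not in seen:
                seen[nxt] = seen[node] + 1
                queue.append(nxt)
    return seen.get(b)


def oracle_exhibits(label_tokens, lr_tokens) -> bool:
    """String-level containment with explicit token boundaries."""
    return f" {' '.join(lr_tokens)} " in f" {' '.join(label_tokens)} "
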