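"""In-memory ontology model and taxonomic / axiom-graph primitives.

The model keeps two directed edge sets over named classes:

* ``subclass_edges`` — asserted ``rdfs:subClassOf`` between *named* classes,
  oriented child -> parent.  The taxonomy lives here: descendants, depth and
  taxonomic distance are defined over these edges alone.
* ``semantic_edges`` — the decomposition of every ``owl:subClassOf`` and
  ``owl:equivalentClass`` axiom into directed edges between named classes.
  For an axiom ``A ⊑ E`` (or ``A ≡ E``) every named class reachable inside
  the expression ``E`` — conjuncts of intersections and fillers of
  existential restrictions, at any nesting depth — yields an edge from ``A``
  to that class.  The edge is tagged ``non-hierarchical`` when it passed
  through an object-property restriction (``∃p.C``) and ``hierarchical``
  otherwise.  Equivalence axioms additionally yield the reverse edges.

Two classes are *semantically related* when a directed path exists over the
semantic edges from one to the other in either orientation.  Directionality
matters: siblings that only share an ancestor are not related, because no
directed path runs between them.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
import networkx as nx

OWL_THING = "http://www.w3.org/2002/07/owl#Thing"
OWL_NOTHING = "http://www.w3.org/2002/07/owl#Nothing"
BUILTIN_CLASSES = frozenset({OWL_THING, OWL_NOTHING})

#: Root synthesized over orphan classes when the ontology asserts no common root.
VIRTUAL_ROOT = "urn:ontoaudit:virtual-root"

HIERARCHICAL = "hierarchical"
NON_HIERARCHICAL = "non-hierarchical"


class OntologyError(Exception):
    """Base class for model-level failures."""


class UnknownEntityError(OntologyError, KeyError):
    """A class IRI was queried that is not declared in the graph."""


@dataclass(frozen=True)
class Annotation:
    """One deduplicated annotation assertion: (property, literal, language)."""

    prop: str
    value: str
    lang: str | None = None


@dataclass
class OntologyGraph:
    """A parsed ontology reduced to what the audit metrics consume.

    ``classes`` excludes the OWL built-ins (owl:Thing, owl:Nothing) and any
    synthesized virtual root; ``root`` may nevertheless name one of those,
    in which case it participates in traversals but not in entity counts.
    """

    classes: set[str] = field(default_factory=set)
    object_properties: set[str] = field(default_factory=set)
    datatype_properties: set[str] = field(default_factory=set)
    annotation_properties: set[str] = field(default_factory=set)
    annotations: dict[str, set[Annotation]] = field(default_factory=dict)
    subclass_edges: set[tuple[str, str]] = field(default_factory=set)
    #: (source, target) -> HIERARCHICAL | NON_HIERARCHICAL
    semantic_edges: dict[tuple[str, str], str] = field(default_factory=dict)
    root: str = OWL_THING

    # ---------------------------------------------------------------- build

    def add_class(self, iri: str, label: str | None = None,
                  label_prop: str = "http://www.w3.org/2000/01/rdf-schema#label") -> str:
        if iri not in BUILTIN_CLASSES and iri != VIRTUAL_ROOT:
            self.classes.add(iri)
        if label is not None:
            self.add_annotation(iri, label_prop, label)
        return iri

    def add_annotation(self, entity: str, prop: str, value: str,
                       lang: str | None = None) -> None:
        self.annotations.setdefault(entity, set()).add(Annotation(prop, value, lang))

    def add_subclass_of(self, sub: str, sup: str) -> None:
        """Assert ``sub ⊑ sup`` between named classes (also a semantic edge)."""
        if sub == sup:
            return
        self.subclass_edges.add((sub, sup))
        self._add_semantic(sub, sup, HIERARCHICAL)

    def add_restriction_link(self, src: str, tgt: str) -> None:
        """Semantic edge decomposed from an existential restriction filler."""
        self._add_semantic(src, tgt, NON_HIERARCHICAL)

    def add_equivalence(self, a: str, b: str,
                        kind: str = HIERARCHICAL) -> None:
        """Edges in both directions, as equivalence axioms contribute them."""
        self._add_semantic(a, b, kind)
        self._add_semantic(b, a, kind)

    def _add_semantic(self, src: str, tgt: str, kind: str) -> None:
        if src == tgt:
            return
        # A hierarchical derivation wins over a non-hierarchical one.
        prev = self.semantic_edges.get((src, tgt))
        if prev != HIERARCHICAL:
            self.semantic_edges[(src, tgt)] = kind

    # ---------------------------------------------------------------- query

    @property
    def nodes(self) -> set[str]:
        """All traversable class nodes, including a non-domain root."""
        return self.classes | {self.root}

    def require_class(self, iri: str) -> None:
        if iri not in self.classes and iri != self.root:
            raise UnknownEntityError(f"unknown class: {iri}")

    def labels_of(self, entity: str, prop: str) -> list[str]:
        """All literal values asserted for ``entity`` under ``prop``, sorted."""
        anns = self.annotations.get(entity, ())
        return sorted(a.value for a in anns if a.prop == prop)

    def parents(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {}
        for sub, sup in self.subclass_edges:
            adj.setdefault(sub, []).append(sup)
        return adj

    def children(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {}
        for sub, sup in self.subclass_edges:
            adj.setdefault(sup, []).append(sub)
        return adj

    def semantic_successors(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {}
        for (src, tgt) in self.semantic_edges:
            adj.setdefault(src, []).append(tgt)
        return adj

    def root_children(self) -> list[str]:
        """Direct subclasses of the root: the top-level hierarchies."""
        return sorted(sub for sub, sup in self.subclass_edges if sup == self.root)

    # ------------------------------------------------------------- validate

    def validate(self) -> None:
        """Raise :class:`OntologyError` when a structural invariant fails."""
        nodes = self.nodes
        for sub, sup in self.subclass_edges:
            if sub not in nodes or sup not in nodes:
                raise OntologyError(f"subclass edge endpoint undeclared: {sub} -> {sup}")
            if (sub, sup) not in self.semantic_edges:
                raise OntologyError(f"subclass edge missing from semantic edges: {sub} -> {sup}")
        for src, tgt in self.semantic_edges:
            if src not in nodes or tgt not in nodes:
                raise OntologyError(f"semantic edge endpoint undeclared: {src} -> {tgt}")
        dg = nx.DiGraph((s, t) for s, t in self.subclass_edges if s != t)
        if not nx.is_directed_acyclic_graph(dg):
            raise OntologyError("subclass relation is cyclic")


# -------------------------------------------------------------------- BFS


def _bfs_layers(adj: dict[str, list[str]], start: str) -> dict[str, int]:
    """Distance (edge count) from ``start`` to every reachable node."""
    dist = {start: 0}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for nxt in adj.get(node, ()):
            if nxt not in dist:
                dist[nxt] = dist[node] + 1
                queue.append(nxt)
    return dist


def transitive_descendants(graph: OntologyGraph, c: str) -> set[str]:
    """All classes below ``c`` in the asserted taxonomy (``c`` excluded)."""
    graph.require_class(c)
    reached = _bfs_layers(graph.children(), c)
    reached.pop(c)
    return set(reached)


def class_depth(graph: OntologyGraph, c: str) -> int | None:
    """Shortest subclass-path length from ``c`` up to the root; None if detached."""
    graph.require_class(c)
    if c == graph.root:
        return 0
    return _bfs_layers(graph.parents(), c).get(graph.root)


def all_depths(graph: OntologyGraph) -> dict[str, int]:
    """Depth of every root-reachable class, by one breadth-first sweep."""
    return _bfs_layers(graph.children(), graph.root)


def taxonomic_distance(graph: OntologyGraph, a: str, b: str) -> int | None:
    """Shortest path length between two classes following is-a links only.

    Each step may traverse a subclass edge in either orientation, so
    ancestor-descendant paths and paths through a common ancestor both
    count.  None when no is-a path connects the two classes.
    """
    graph.require_class(a)
    graph.require_class(b)
    if a == b:
        return 0
    undirected: dict[str, list[str]] = {}
    for sub, sup in graph.subclass_edges:
        undirected.setdefault(sub, []).append(sup)
        undirected.setdefault(sup, []).append(sub)
    return _bfs_layers(undirected, a).get(b)


def distances_from(graph: OntologyGraph, c: str) -> dict[str, int]:
    """Taxonomic distance from ``c`` to every is-a-connected class."""
    graph.require_class(c)
    undirected: dict[str, list[str]] = {}
    for sub, sup in graph.subclass_edges:
        undirected.setdefault(sub, []).append(sup)
        undirected.setdefault(sup, []).append(sub)
    return _bfs_layers(undirected, c)


def semantic_reach(graph: OntologyGraph, c: str) -> tuple[set[str], set[str]]:
    """(classes reachable from ``c``, classes that reach ``c``) over semantic edges."""
    graph.require_class(c)
    forward = set(_bfs_layers(graph.semantic_successors(), c))
    reverse_adj: dict[str, list[str]] = {}
    for (src, tgt) in graph.semantic_edges:
        reverse_adj.setdefault(tgt, []).append(src)
    backward = set(_bfs_layers(reverse_adj, c))
    return forward, backward


def semantically_related(graph: OntologyGraph, c1: str, c2: str) -> bool:
    """True iff a directed semantic path runs c1->c2 or c2->c1.

    Reachability is reflexive: every class is related to itself.
    """
    graph.require_class(c1)
    graph.require_class(c2)
    if c1 == c2:
        return True
    forward = _bfs_layers(graph.semantic_successors(), c1)
    if c2 in forward:
        return True
    return c1 in _bfs_layers(graph.semantic_successors(), c2)


def ensure_root(graph: OntologyGraph, requested: str | None = None) -> OntologyGraph:
    """Resolve the depth origin of a freshly loaded graph, in place.

    Order of preference: an explicitly requested root; ``owl:Thing`` when it
    has asserted children; the single orphan class when exactly one class
    has no named superclass; otherwise a virtual root is synthesized with
    every orphan class attached to it.
    """
    if requested is not None:
        if requested not in graph.classes and requested != OWL_THING:
            raise OntologyError(f"requested root is not a declared class: {requested}")
        graph.root = requested
        return graph
    supers = {sup for _, sup in graph.subclass_edges}
    if OWL_THING in supers:
        graph.root = OWL_THING
        return graph
    has_parent = {sub for sub, _ in graph.subclass_edges}
    orphans = sorted(graph.classes - has_parent)
    if len(orphans) == 1:
        graph.root = orphans[0]
    else:
        graph.root = VIRTUAL_ROOT
        for orphan in orphans:
            graph.add_subclass_of(orphan, VIRTUAL_ROOT)
    return graph
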