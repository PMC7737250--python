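"""Reading and writing ontologies.

RDF/XML is parsed with :mod:`rdflib`; OBO 1.4 with :mod:`obonet`; OWL
Functional Syntax with a small reader local to this module that covers the
axiom types the audit consumes (declarations, SubClassOf, EquivalentClasses,
AnnotationAssertion, with ObjectIntersectionOf and ObjectSomeValuesFrom
expressions).  Class identity is always the full IRI; labels are never used
as identifiers.

Every ``owl:subClassOf`` / ``owl:equivalentClass`` axiom is decomposed into
directed semantic edges as described in :mod:`ontoaudit.model`: for
``A ⊑ B ⊓ ∃hasLaterality.Left`` the graph gains A->B (hierarchical) and
A->Left (non-hierarchical); an equivalence additionally gains the reverse
edges.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterator

import rdflib
from rdflib import BNode, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .model import (
    BUILTIN_CLASSES,
    HIERARCHICAL,
    NON_HIERARCHICAL,
    VIRTUAL_ROOT,
    OntologyGraph,
    ensure_root,
)

RDFS_LABEL = str(RDFS.label)

DIALECTS = ("rdfxml", "functional", "obo", "auto")


class FormatError(Exception):
    """The input file could not be parsed in the stated dialect."""


class ConfigurationError(Exception):
    """An unsupported dialect or inconsistent option was requested."""


# --------------------------------------------------------------------------
# public entry point
# --------------------------------------------------------------------------


def load_ontology(path: str | Path, dialect: str = "auto",
                  root: str | None = None) -> OntologyGraph:
    """Parse an ontology file into an :class:`OntologyGraph`.

    ``dialect`` is one of ``rdfxml``, ``functional``, ``obo`` or ``auto``
    (sniffed from the file content).  ``root`` optionally forces the depth
    origin; otherwise it is resolved per :func:`ontoaudit.model.ensure_root`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in DIALECTS:
        raise ConfigurationError(
            f"unsupported dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    if dialect == "rdfxml":
        graph = _load_rdfxml(path)
    elif dialect == "functional":
        graph = _load_functional(path.read_text())
    else:
        graph = _load_obo(path)
    graph = ensure_root(graph, root)
    graph.validate()
    return graph


def _sniff_dialect(path: Path) -> str:
    head = path.read_text(errors="replace")[:4096].lstrip()
    if head.startswith("<"):
        return "rdfxml"
    if head.startswith("format-version") or "[Term]" in head:
        return "obo"
    if head.startswith(("Prefix(", "Ontology(")):
        return "functional"
    raise FormatError(f"cannot sniff ontology dialect of {path}")


# --------------------------------------------------------------------------
# RDF/XML via rdflib
# --------------------------------------------------------------------------


def _load_rdfxml(path: Path) -> OntologyGraph:
    rg = rdflib.Graph()
    try:
        rg.parse(path, format="xml")
    except Exception as exc:  # rdflib raises SAX/xml errors with position info
        raise FormatError(f"RDF/XML parse failure in {path}: {exc}") from exc
    return graph_from_rdflib(rg)


def graph_from_rdflib(rg: rdflib.Graph) -> OntologyGraph:
    """Convert a parsed rdflib graph to the audit model (root unresolved)."""
    g = OntologyGraph()
    for s in rg.subjects(RDF.type, OWL.Class):
        if isinstance(s, URIRef):
            g.add_class(str(s))
    for s in rg.subjects(RDF.type, OWL.ObjectProperty):
        if isinstance(s, URIRef):
            g.object_properties.add(str(s))
    for s in rg.subjects(RDF.type, OWL.DatatypeProperty):
        if isinstance(s, URIRef):
            g.datatype_properties.add(str(s))
    for s in rg.subjects(RDF.type, OWL.AnnotationProperty):
        if isinstance(s, URIRef):
            g.annotation_properties.add(str(s))

    # annotation assertions: any literal-valued triple on a named entity
    for s, p, o in rg:
        if isinstance(s, URIRef) and isinstance(o, Literal):
            g.add_annotation(str(s), str(p), str(o), o.language)

    for s, o in rg.subject_objects(RDFS.subClassOf):
        if not isinstance(s, URIRef):
            continue
        subject = str(s)
        if isinstance(o, URIRef):
            tgt = str(o)
            g.add_class(subject)
            if tgt not in BUILTIN_CLASSES:
                g.add_class(tgt)
            g.add_subclass_of(subject, tgt)
        else:
            g.add_class(subject)
            for tgt, via_restriction in _decompose(rg, o):
                g.add_class(tgt)
                if via_restriction:
                    g.add_restriction_link(subject, tgt)
                else:
                    g._add_semantic(subject, tgt, HIERARCHICAL)

    for s, o in rg.subject_objects(OWL.equivalentClass):
        pairs = [(s, o), (o, s)]
        for a, b in pairs:
            if not isinstance(a, URIRef):
                continue
            subject = str(a)
            g.add_class(subject)
            for tgt, via_restriction in _decompose(rg, b):
                g.add_class(tgt)
                kind = NON_HIERARCHICAL if via_restriction else HIERARCHICAL
                g.add_equivalence(subject, tgt, kind)
    return g


def _decompose(rg: rdflib.Graph, node,
               via_restriction: bool = False) -> Iterator[tuple[str, bool]]:
    """Named classes inside a class expression, flagged when a filler."""
    if isinstance(node, URIRef):
        iri = str(node)
        if iri not in BUILTIN_CLASSES:
            yield iri, via_restriction
        return
    if not isinstance(node, BNode):
        return
    filler = rg.value(node, OWL.someValuesFrom)
    if filler is not None:
        yield from _decompose(rg, filler, True)
    for prop in (OWL.intersectionOf, OWL.unionOf):
        lst = rg.value(node, prop)
        if lst is not None:
            for member in rg.items(lst):
                yield from _decompose(rg, member, via_restriction)


# --------------------------------------------------------------------------
# OWL Functional Syntax (minimal reader)
# --------------------------------------------------------------------------

_OFN_TOKEN = re.compile(
    r"""\s*(?:
        (?P<open>\()|(?P<close>\))|
        (?P<string>"(?:[^"\\]|\\.)*"(?:\^\^\S+|@[A-Za-z-]+)?)|
        (?P<iri><[^>]*>)|
        (?P<atom>[^\s()"<>]+)
    )""",
    re.VERBOSE,
)


def _tokenize_ofn(text: str) -> Iterator[str]:
    pos = 0
    while pos < len(text):
        m = _OFN_TOKEN.match(text, pos)
        if not m:
            remainder = text[pos:].strip()
            if not remainder:
                return
            raise FormatError(f"functional-syntax token error near: {remainder[:40]!r}")
        pos = m.end()
        token = m.group().strip()
        if token:
            yield token


def _parse_sexprs(tokens: Iterator[str]):
    """Group a flat token stream into (head, children) trees."""
    stack: list[list] = [[]]
    pending: str | None = None
    for tok in tokens:
        if tok == "(":
            node = [pending, []]
            pending = None
            stack[-1].append(node)
            stack.append(node[1])
        elif tok == ")":
            if len(stack) == 1:
                raise FormatError("unbalanced ')' in functional syntax")
            if pending is not None:
                stack[-1].append(pending)
                pending = None
            stack.pop()
        else:
            if pending is not None:
                stack[-1].append(pending)
            pending = tok
    if pending is not None:
        stack[-1].append(pending)
    if len(stack) != 1:
        raise FormatError("unbalanced '(' in functional syntax")
    return stack[0]


def _load_functional(text: str) -> OntologyGraph:
    g = OntologyGraph()
    # rdf, rdfs, xsd and owl are predeclared in OWL functional syntax
    prefixes: dict[str, str] = {
        "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
        "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
        "xsd": "http://www.w3.org/2001/XMLSchema#",
        "owl": "http://www.w3.org/2002/07/owl#",
    }
    try:
        forms = _parse_sexprs(_tokenize_ofn(text))
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"functional-syntax parse failure: {exc}") from exc

    def expand(atom: str) -> str:
        if atom.startswith("<") and atom.endswith(">"):
            return atom[1:-1]
        if ":" in atom:
            prefix, local = atom.split(":", 1)
            if prefix in prefixes:
                return prefixes[prefix] + local
        return atom

    def handle_axiom(head: str, args: list) -> None:
        if head == "Prefix":
            # Prefix(skos:=<http://...>) — the IRI tokenizes separately
            decl = args[0] if args else ""
            if isinstance(decl, str) and ":=" in decl:
                prefix, iri = decl.split(":=", 1)
                if not iri and len(args) > 1 and isinstance(args[1], str):
                    iri = args[1]
                prefixes[prefix] = iri.strip("<>")
        elif head == "Ontology":
            for item in args:
                if isinstance(item, list):
                    handle_axiom(item[0], item[1])
        elif head == "Declaration":
            kind, inner = args[0][0], args[0][1]
            iri = expand(inner[0])
            if kind == "Class":
                g.add_class(iri)
            elif kind == "ObjectProperty":
                g.object_properties.add(iri)
            elif kind == "DataProperty":
                g.datatype_properties.add(iri)
            elif kind == "AnnotationProperty":
                g.annotation_properties.add(iri)
        elif head == "SubClassOf" and len(args) == 2:
            sub, sup = args
            if isinstance(sub, str):
                subject = expand(sub)
                g.add_class(subject)
                if isinstance(sup, str):
                    tgt = expand(sup)
                    if tgt not in BUILTIN_CLASSES:
                        g.add_class(tgt)
                    g.add_subclass_of(subject, tgt)
                else:
                    for tgt, via in _decompose_ofn(sup, expand):
                        g.add_class(tgt)
                        if via:
                            g.add_restriction_link(subject, tgt)
                        else:
                            g._add_semantic(subject, tgt, HIERARCHICAL)
        elif head == "EquivalentClasses":
            named = [a for a in args if isinstance(a, str)]
            for subject_atom in named:
                subject = expand(subject_atom)
                g.add_class(subject)
                for other in args:
                    if other is subject_atom:
                        continue
                    for tgt, via in _decompose_ofn(other, expand):
                        if tgt == subject:
                            continue
                        g.add_class(tgt)
                        kind = NON_HIERARCHICAL if via else HIERARCHICAL
                        g.add_equivalence(subject, tgt, kind)
        elif head == "AnnotationAssertion" and len(args) == 3:
            prop, subject, value = args
            if isinstance(value, str) and value.startswith('"'):
                lang = None
                body = value
                if "@" in body and not body.endswith('"'):
                    body, lang = body.rsplit("@", 1)
                body = re.sub(r"\^\^\S+$", "", body)
                literal = body[1:-1].replace('\\"', '"').replace("\\\\", "\\")
                g.add_annotation(expand(subject), expand(prop), literal, lang)
        # unrecognized axioms are skipped

    for form in forms:
        if isinstance(form, list):
            handle_axiom(form[0], form[1])
    return g


def _decompose_ofn(node, expand) -> Iterator[tuple[str, bool]]:
    if isinstance(node, str):
        iri = expand(node)
        if iri not in BUILTIN_CLASSES:
            yield iri, False
        return
    head, args = node
    if head == "ObjectSomeValuesFrom" and len(args) == 2:
        for iri, _ in _decompose_ofn(args[1], expand):
            yield iri, True
    elif head in ("ObjectIntersectionOf", "ObjectUnionOf"):
        for member in args:
            yield from _decompose_ofn(member, expand)


# --------------------------------------------------------------------------
# OBO 1.4 via obonet
# --------------------------------------------------------------------------

OBO_PURL = "http://purl.obolibrary.org/obo/"
IAO_DEFINITION = "http://purl.obolibrary.org/obo/IAO_0000115"
OBO_SYNONYM_SCOPES = {
    "EXACT": "http://www.geneontology.org/formats/oboInOwl#hasExactSynonym",
    "BROAD": "http://www.geneontology.org/formats/oboInOwl#hasBroadSynonym",
    "NARROW": "http://www.geneontology.org/formats/oboInOwl#hasNarrowSynonym",
    "RELATED": "http://www.geneontology.org/formats/oboInOwl#hasRelatedSynonym",
}

_QUOTED = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _obo_iri(term_id: str) -> str:
    if term_id.startswith("http://") or term_id.startswith("https://"):
        return term_id
    return OBO_PURL + term_id.replace(":", "_")


def _load_obo(path: Path) -> OntologyGraph:
    import obonet

    try:
        net = obonet.read_obo(str(path))
    except Exception as exc:
        raise FormatError(f"OBO parse failure in {path}: {exc}") from exc
    g = OntologyGraph()
    for node, data in net.nodes(data=True):
        iri = _obo_iri(node)
        g.add_class(iri)
        if "name" in data:
            g.add_annotation(iri, RDFS_LABEL, data["name"])
        if "def" in data:
            m = _QUOTED.match(data["def"])
            g.add_annotation(iri, IAO_DEFINITION,
                             m.group(1) if m else data["def"])
        for raw in data.get("synonym", ()):
            m = _QUOTED.match(raw)
            if not m:
                continue
            scope = raw[m.end():].strip().split(" ")[0]
            prop = OBO_SYNONYM_SCOPES.get(scope, OBO_SYNONYM_SCOPES["RELATED"])
            g.add_annotation(iri, prop, m.group(1))
    # obonet orients is_a edges child -> parent
    for child, parent, key in net.edges(keys=True):
        if key == "is_a":
            g.add_subclass_of(_obo_iri(child), _obo_iri(parent))
    return g


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------

DEFAULT_LINK_PROPERTY = "urn:ontoaudit:linkedTo"


def to_rdfxml(graph: OntologyGraph, path: str | Path,
              link_property: str = DEFAULT_LINK_PROPERTY) -> None:
    """Serialize the model as OWL RDF/XML so :func:`load_ontology` round-trips.

    Subclass edges become ``rdfs:subClassOf`` triples; non-hierarchical
    semantic edges become ``s ⊑ ∃link.t`` restrictions; paired hierarchical
    non-subclass edges become ``owl:equivalentClass``.  Edges attached to a
    synthesized virtual root are dropped (they are not asserted content).
    """
    rg = rdflib.Graph()
    rg.bind("owl", OWL)
    rg.bind("rdfs", RDFS)
    for cls in sorted(graph.classes):
        rg.add((URIRef(cls), RDF.type, OWL.Class))
    for prop in sorted(graph.object_properties):
        rg.add((URIRef(prop), RDF.type, OWL.ObjectProperty))
    for prop in sorted(graph.datatype_properties):
        rg.add((URIRef(prop), RDF.type, OWL.DatatypeProperty))
    for prop in sorted(graph.annotation_properties):
        rg.add((URIRef(prop), RDF.type, OWL.AnnotationProperty))
    for entity in sorted(graph.annotations):
        for ann in sorted(graph.annotations[entity],
                          key=lambda a: (a.prop, a.value, a.lang or "")):
            rg.add((URIRef(entity), URIRef(ann.prop),
                    Literal(ann.value, lang=ann.lang)))
    for sub, sup in sorted(graph.subclass_edges):
        if VIRTUAL_ROOT in (sub, sup):
            continue
        rg.add((URIRef(sub), RDFS.subClassOf, URIRef(sup)))

    link = URIRef(link_property)
    emitted_equiv: set[tuple[str, str]] = set()
    n_restrictions = 0
    for (src, tgt), kind in sorted(graph.semantic_edges.items()):
        if (src, tgt) in graph.subclass_edges or VIRTUAL_ROOT in (src, tgt):
            continue
        if kind == NON_HIERARCHICAL:
            if (link, RDF.type, OWL.ObjectProperty) not in rg:
                rg.add((link, RDF.type, OWL.ObjectProperty))
            # stable blank-node ids keep the serialization byte-reproducible
            restriction = BNode(f"restriction{n_restrictions:06d}")
            n_restrictions += 1
            rg.add((restriction, RDF.type, OWL.Restriction))
            rg.add((restriction, OWL.onProperty, link))
            rg.add((restriction, OWL.someValuesFrom, URIRef(tgt)))
            rg.add((URIRef(src), RDFS.subClassOf, restriction))
        else:
            pair = tuple(sorted((src, tgt)))
            if (tgt, src) in graph.semantic_edges and pair not in emitted_equiv:
                emitted_equiv.add(pair)
                rg.add((URIRef(pair[0]), OWL.equivalentClass, URIRef(pair[1])))
            elif (tgt, src) not in graph.semantic_edges:
                rg.add((URIRef(src), RDFS.subClassOf, URIRef(tgt)))
    rg.serialize(destination=str(path), format="pretty-xml")
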