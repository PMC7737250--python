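"""Reference fixtures: the worked-example taxonomy and a synthetic generator.

``figure1_ontology`` builds the six-class procedure taxonomy used throughout
the documentation to illustrate both structural-accuracy metrics; it is
small enough to verify every number by hand.

``generate_synthetic_ontology`` emits a seeded random taxonomy with exact
ground truth for every metric.  Labels are drawn from a closed vocabulary of
fresh, never-reused tokens, so whether one label exhibits another is
controlled exactly by construction rather than probabilistically: a child
either extends its parent's label (and exhibits it) or starts from fresh
tokens (and cannot collide with anything).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import RDFS_LABEL, to_rdfxml
from .model import OntologyGraph

FIG1 = "http://example.org/fig1#"

SKOS_PREF_LABEL = "http://www.w3.org/2004/02/skos/core#prefLabel"
SKOS_ALT_LABEL = "http://www.w3.org/2004/02/skos/core#altLabel"
SKOS_DEFINITION = "http://www.w3.org/2004/02/skos/core#definition"

SYNTH = "urn:synth:"
LINK_PROPERTY = SYNTH + "linkedTo"


class GenerationError(Exception):
    """The requested synthetic spec cannot be realized."""


def figure1_ontology() -> OntologyGraph:
    """The six-class worked-example taxonomy.

    root > {Procedure, Cosmetic procedure}; Procedure > Administrative
    procedure > {Death administrative procedure, Biopsy administration}.
    With a permissive coverage it has exactly two LR classes (Procedure and
    Administrative procedure), an LSLD value of 3/4 and a systematic-naming
    value of 3/5.
    """
    g = OntologyGraph(root=FIG1 + "Root")
    g.add_class(FIG1 + "Root", "SNOMED CT Concept")
    g.add_class(FIG1 + "Procedure", "Procedure")
    g.add_class(FIG1 + "CosmeticProcedure", "Cosmetic procedure")
    g.add_class(FIG1 + "AdministrativeProcedure", "Administrative procedure")
    g.add_class(FIG1 + "DeathAdministrativeProcedure",
                "Death administrative procedure")
    g.add_class(FIG1 + "BiopsyAdministration", "Biopsy administration")
    g.add_subclass_of(FIG1 + "Procedure", FIG1 + "Root")
    g.add_subclass_of(FIG1 + "CosmeticProcedure", FIG1 + "Root")
    g.add_subclass_of(FIG1 + "AdministrativeProcedure", FIG1 + "Procedure")
    g.add_subclass_of(FIG1 + "DeathAdministrativeProcedure",
                      FIG1 + "AdministrativeProcedure")
    g.add_subclass_of(FIG1 + "BiopsyAdministration",
                      FIG1 + "AdministrativeProcedure")
    g.validate()
    return g


# --------------------------------------------------------------------------
# synthetic generator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthSpec:
    """Conditions for one synthetic ontology; generation is a pure function
    of this spec (the seed lives inside it).

    ``p_name_inherit`` — probability an anchor's child label extends the
    anchor label with a fresh token (making it a positive systematic-naming
    case); may be one float or one per hierarchy.
    ``p_axiom_link`` — probability a lexical cousin (a class in another
    hierarchy whose label contains the anchor label) gets an existential-
    restriction axiom linking it to the anchor (making it a positive LSLD
    case); same shape.
    ``mean_children`` — Poisson mean of children per anchor.
    ``n_cousins_per_anchor`` — fixed cousin count; because cousins always
    exhibit the anchor label, it is also the guaranteed minimum support of
    every anchor, keeping anchors detectable at the default coverage for
    ontologies up to ~1000 x this size.
    ``annotation_rates`` — Poisson means of extra names / synonyms /
    descriptions per entity, beyond the one rdfs:label every entity carries.
    """

    n_classes: int = 2000
    n_hierarchies: int = 2
    mean_children: float = 8.0
    n_cousins_per_anchor: int = 4
    p_name_inherit: float | tuple[float, ...] = 0.5
    p_axiom_link: float | tuple[float, ...] = 0.5
    annotation_rates: tuple[float, float, float] = (1.0, 0.5, 0.1)
    seed: int = 0

    def rate_per_hierarchy(self, value) -> tuple[float, ...]:
        if isinstance(value, (int, float)):
            value = (float(value),) * self.n_hierarchies
        value = tuple(float(v) for v in value)
        if len(value) != self.n_hierarchies:
            raise GenerationError(
                f"expected {self.n_hierarchies} per-hierarchy rates, got {len(value)}")
        if any(not (0.0 <= v <= 1.0) for v in value):
            raise GenerationError(f"probabilities must lie in [0, 1]: {value}")
        return value


@dataclass
class GroundTruth:
    """Exact bookkeeping of what the generator planted.

    ``sysnaming[lr][subject]`` / ``lsld[lr][subject]`` record the planted
    polarity of every case; ``annotation_totals[kind][aspect]`` and
    ``entity_counts[kind]`` reproduce the readability numerators and
    denominators.
    """

    lr_classes: list[str] = field(default_factory=list)
    hierarchy_of: dict[str, str] = field(default_factory=dict)
    sysnaming: dict[str, dict[str, bool]] = field(default_factory=dict)
    lsld: dict[str, dict[str, bool]] = field(default_factory=dict)
    annotation_totals: dict[str, dict[str, int]] = field(default_factory=dict)
    entity_counts: dict[str, int] = field(default_factory=dict)

    def pooled(self, metric: str) -> tuple[int, int]:
        """(positives, total cases) planted for ``metric``."""
        table = self.sysnaming if metric == "systematic_naming" else self.lsld
        pos = sum(v for cases in table.values() for v in cases.values())
        total = sum(len(cases) for cases in table.values())
        return pos, total

    def expected_ratio(self, kind: str, aspect: str) -> float | None:
        denom = self.entity_counts.get(kind, 0)
        if denom == 0:
            return None
        return self.annotation_totals[kind][aspect] / denom

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "lr_classes": self.lr_classes,
            "hierarchy_of": self.hierarchy_of,
            "sysnaming": self.sysnaming,
            "lsld": self.lsld,
            "annotation_totals": self.annotation_totals,
            "entity_counts": self.entity_counts,
        }, indent=2, sort_keys=True))


def generate_synthetic_ontology(spec: SynthSpec) -> tuple[OntologyGraph, GroundTruth]:
    """Generate a random taxonomy with known metric ground truth.

    Layout: a root, ``n_hierarchies`` top-level heads, and under them
    "anchor" classes with unique single-token labels.  Each anchor gets a
    Poisson number of children (its only descendants) and a fixed number of
    lexical cousins placed under a *different* head.  Children inherit the
    anchor label with probability ``p_name_inherit``; cousins always carry
    the anchor label and are axiomatically linked to the anchor with
    probability ``p_axiom_link``.  The anchors are exactly the LR classes
    whenever the coverage threshold is at most the cousin count.
    """
    if spec.n_classes < 1 + spec.n_hierarchies + 1:
        raise GenerationError(f"n_classes={spec.n_classes} too small for "
                              f"{spec.n_hierarchies} hierarchies")
    p_inherit = spec.rate_per_hierarchy(spec.p_name_inherit)
    p_link = spec.rate_per_hierarchy(spec.p_axiom_link)
    block = 1 + spec.mean_children + spec.n_cousins_per_anchor
    n_anchors = max(1, int(round((spec.n_classes - 1 - spec.n_hierarchies) / block)))

    rng = np.random.default_rng(spec.seed)
    counter = iter(range(10 ** 9))

    def fresh_token() -> str:
        return f"t{next(counter):06d}"

    g = OntologyGraph(root=SYNTH + "root")
    truth = GroundTruth()
    g.add_class(SYNTH + "root", "root " + fresh_token())
    heads = []
    for i in range(spec.n_hierarchies):
        head = f"{SYNTH}h{i}"
        g.add_class(head, f"hierarchy {fresh_token()}")
        g.add_subclass_of(head, g.root)
        heads.append(head)

    g.object_properties.add(LINK_PROPERTY)
    g.add_annotation(LINK_PROPERTY, RDFS_LABEL, "linked to")

    for i in range(n_anchors):
        h_idx = i % spec.n_hierarchies
        anchor = f"{SYNTH}a{i:05d}"
        anchor_label = fresh_token()
        g.add_class(anchor, anchor_label)
        g.add_subclass_of(anchor, heads[h_idx])
        truth.lr_classes.append(anchor)
        truth.hierarchy_of[anchor] = heads[h_idx]
        truth.sysnaming[anchor] = {}
        truth.lsld[anchor] = {}

        n_children = int(rng.poisson(spec.mean_children))
        for j in range(n_children):
            child = f"{SYNTH}a{i:05d}c{j:03d}"
            inherits = bool(rng.random() < p_inherit[h_idx])
            label = (f"{anchor_label} {fresh_token()}" if inherits
                     else f"{fresh_token()} {fresh_token()}")
            g.add_class(child, label)
            g.add_subclass_of(child, anchor)
            truth.sysnaming[anchor][child] = inherits
            if inherits:
                # an inheriting child exhibits the LR and, being a subclass,
                # is always semantically related: an always-positive LSLD case
                truth.lsld[anchor][child] = True

        cousin_head = heads[(h_idx + 1) % spec.n_hierarchies]
        for j in range(spec.n_cousins_per_anchor):
            cousin = f"{SYNTH}a{i:05d}x{j:03d}"
            g.add_class(cousin, f"{fresh_token()} {anchor_label}")
            g.add_subclass_of(cousin, cousin_head)
            linked = bool(rng.random() < p_link[h_idx])
            if linked:
                g.add_restriction_link(cousin, anchor)
            truth.lsld[anchor][cousin] = linked

    _add_annotations(g, truth, spec, rng)
    g.validate()
    return g, truth


def _add_annotations(g: OntologyGraph, truth: GroundTruth, spec: SynthSpec,
                     rng: np.random.Generator) -> None:
    r_names, r_syns, r_descs = spec.annotation_rates
    kinds = {"class": sorted(g.classes),
             "object_property": sorted(g.object_properties),
             "datatype_property": [],
             "annotation_property": []}
    truth.entity_counts = {k: len(v) for k, v in kinds.items()}
    truth.annotation_totals = {
        k: {"names": 0, "synonyms": 0, "descriptions": 0} for k in kinds}
    for kind, entities in kinds.items():
        for entity in entities:
            # the canonical rdfs:label counts as one name
            totals = truth.annotation_totals[kind]
            totals["names"] += 1
            for k in range(int(rng.poisson(r_names))):
                g.add_annotation(entity, SKOS_PREF_LABEL, f"name {k} of {entity}")
                totals["names"] += 1
            for k in range(int(rng.poisson(r_syns))):
                g.add_annotation(entity, SKOS_ALT_LABEL, f"synonym {k} of {entity}")
                totals["synonyms"] += 1
            for k in range(int(rng.poisson(r_descs))):
                g.add_annotation(entity, SKOS_DEFINITION, f"description {k} of {entity}")
                totals["descriptions"] += 1


def save_fixture(graph: OntologyGraph, path: str | Path,
                 truth: GroundTruth | None = None) -> None:
    """Write a fixture as OWL RDF/XML (and its ground truth as JSON)."""
    to_rdfxml(graph, path, link_property=LINK_PROPERTY)
    if truth is not None:
        truth.to_json(Path(path).with_suffix(".truth.json"))


# --------------------------------------------------------------------------
# small random ontologies for oracle comparison
# --------------------------------------------------------------------------


def random_ontology(n_classes: int, seed: int, p_extra_parent: float = 0.2,
                    p_link: float = 0.08, p_equiv: float = 0.04,
                    vocabulary: int = 8) -> OntologyGraph:
    """A random small ontology whose graph primitives are brute-forceable.

    Classes ``c0..c{n-1}`` with ``c0`` as root; subclass edges always point
    from a later class to an earlier one, so the taxonomy is acyclic by
    construction.  Random existential-restriction links and equivalences
    add non-tree semantic edges, and labels drawn from a small shared
    vocabulary make lexical regularities (and hence metric cases) appear.
    """
    rng = np.random.default_rng(seed)
    vocab = [f"w{k}" for k in range(vocabulary)]
    g = OntologyGraph(root="urn:rand:c0")
    iris = [f"urn:rand:c{i}" for i in range(n_classes)]
    for i, iri in enumerate(iris):
        n_tokens = int(rng.integers(1, 4))
        label = " ".join(rng.choice(vocab, size=n_tokens))
        g.add_class(iri, f"{label} u{i}" if rng.random() < 0.3 else label)
        if i == 0:
            continue
        parent = iris[int(rng.integers(0, i))]
        g.add_subclass_of(iri, parent)
        if i > 1 and rng.random() < p_extra_parent:
            g.add_subclass_of(iri, iris[int(rng.integers(0, i))])
        if i > 1 and rng.random() < p_link:
            g.add_restriction_link(iri, iris[int(rng.integers(0, i))])
        if i > 1 and rng.random() < p_equiv:
            g.add_equivalence(iri, iris[int(rng.integers(0, i))])
    g.validate()
    return g
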