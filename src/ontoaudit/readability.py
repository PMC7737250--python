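"""Readability metrics: names, synonyms and descriptions per entity kind.

The twelve ratios are total annotation count divided by entity count for
each of {names, synonyms, descriptions} x {class, object property, datatype
property, annotation property}.  Which annotation properties count as a
name, a synonym or a description is governed by an :class:`AnnotationCatalog`;
the default catalog reflects the vocabularies most used across biomedical
ontology repositories (skos, rdfs, schema.org, oboInOwl, IAO, Dublin Core,
NCIT).

An entity kind with no entities yields NA (None), reported distinctly from
a ratio of zero: "no datatype properties" and "datatype properties without
annotations" are different findings.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import BUILTIN_CLASSES, VIRTUAL_ROOT, OntologyGraph

DEFAULT_NAME_PROPERTIES = frozenset({
    "http://www.w3.org/2004/02/skos/core#prefLabel",
    "http://www.w3.org/2000/01/rdf-schema#label",
    "http://schema.org/name",
    "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#P108",
})

DEFAULT_SYNONYM_PROPERTIES = frozenset({
    "http://www.w3.org/2004/02/skos/core#altLabel",
    "http://www.geneontology.org/formats/oboInOwl#hasExactSynonym",
    "http://www.geneontology.org/formats/oboInOwl#hasRelatedSynonym",
    "http://www.geneontology.org/formats/oboInOwl#hasBroadSynonym",
    "http://www.geneontology.org/formats/oboInOwl#hasNarrowSynonym",
    "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#P90",
    "http://purl.obolibrary.org/obo/IAO_0000118",
})

DEFAULT_DESCRIPTION_PROPERTIES = frozenset({
    "http://purl.obolibrary.org/obo/IAO_0000115",
    "http://www.w3.org/2004/02/skos/core#definition",
    "http://www.w3.org/2000/01/rdf-schema#comment",
    "http://purl.org/dc/elements/1.1/description",
    "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#P97",
})

ENTITY_KINDS = ("class", "object_property", "datatype_property", "annotation_property")
ASPECTS = ("names", "synonyms", "descriptions")


class CatalogError(Exception):
    """The three catalog sets are not pairwise disjoint."""


@dataclass(frozen=True)
class AnnotationCatalog:
    """The three annotation-property sets driving the readability ratios."""

    name_properties: frozenset[str] = DEFAULT_NAME_PROPERTIES
    synonym_properties: frozenset[str] = DEFAULT_SYNONYM_PROPERTIES
    description_properties: frozenset[str] = DEFAULT_DESCRIPTION_PROPERTIES

    def __post_init__(self) -> None:
        sets = (self.name_properties, self.synonym_properties,
                self.description_properties)
        union = set().union(*sets)
        if len(union) != sum(len(s) for s in sets):
            overlap = sorted(
                p for p in union
                if sum(p in s for s in sets) > 1)
            raise CatalogError(f"catalog sets overlap on: {overlap}")

    @property
    def all_properties(self) -> frozenset[str]:
        return self.name_properties | self.synonym_properties | self.description_properties

    def classify(self, prop: str) -> str | None:
        if prop in self.name_properties:
            return "names"
        if prop in self.synonym_properties:
            return "synonyms"
        if prop in self.description_properties:
            return "descriptions"
        return None


@dataclass
class ReadabilityResult:
    """The twelve ratios plus per-entity count distributions.

    ``totals[kind][aspect]`` is the pooled annotation count,
    ``entity_counts[kind]`` the denominator, and ``per_entity[kind][aspect]``
    the list of per-entity counts (box-plot material), index-aligned with
    ``entities[kind]``.
    """

    totals: dict[str, dict[str, int]]
    entity_counts: dict[str, int]
    per_entity: dict[str, dict[str, list[int]]]
    entities: dict[str, list[str]]

    def ratio(self, kind: str, aspect: str) -> float | None:
        denom = self.entity_counts[kind]
        if denom == 0:
            return None
        return self.totals[kind][aspect] / denom

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind in ENTITY_KINDS:
            for aspect in ASPECTS:
                rows.append({
                    "entity_kind": kind,
                    "aspect": aspect,
                    "annotation_count": self.totals[kind][aspect],
                    "entity_count": self.entity_counts[kind],
                    "ratio": self.ratio(kind, aspect),
                })
        return pd.DataFrame(rows)


def _entity_universe(graph: OntologyGraph,
                     catalog: AnnotationCatalog) -> dict[str, list[str]]:
    """Domain entities per kind; built-in vocabulary is not domain content."""
    excluded = BUILTIN_CLASSES | {VIRTUAL_ROOT} | catalog.all_properties
    return {
        "class": sorted(graph.classes - excluded),
        "object_property": sorted(graph.object_properties - excluded),
        "datatype_property": sorted(graph.datatype_properties - excluded),
        "annotation_property": sorted(graph.annotation_properties - excluded),
    }


def annotation_counts(graph: OntologyGraph,
                      catalog: AnnotationCatalog = AnnotationCatalog(),
                      ) -> dict[str, tuple[int, int, int]]:
    """Per-entity (names, synonyms, descriptions) counts.

    Identical repeated assertions are counted once (the model stores
    annotations as a set); language-tagged variants of the same string are
    distinct assertions and count separately.  Assertions whose property is
    outside the catalog are ignored.
    """
    universe = _entity_universe(graph, catalog)
    counts: dict[str, tuple[int, int, int]] = {}
    for kind_entities in universe.values():
        for entity in kind_entities:
            n = s = d = 0
            for ann in graph.annotations.get(entity, ()):
                aspect = catalog.classify(ann.prop)
                if aspect == "names":
                    n += 1
                elif aspect == "synonyms":
                    s += 1
                elif aspect == "descriptions":
                    d += 1
            counts[entity] = (n, s, d)
    return counts


def readability_metrics(graph: OntologyGraph,
                        catalog: AnnotationCatalog = AnnotationCatalog(),
                        ) -> ReadabilityResult:
    """Compute all twelve readability ratios."""
    universe = _entity_universe(graph, catalog)
    counts = annotation_counts(graph, catalog)
    totals = {k: {a: 0 for a in ASPECTS} for k in ENTITY_KINDS}
    per_entity = {k: {a: [] for a in ASPECTS} for k in ENTITY_KINDS}
    for kind in ENTITY_KINDS:
        for entity in universe[kind]:
            n, s, d = counts[entity]
            for aspect, value in zip(ASPECTS, (n, s, d)):
                totals[kind][aspect] += value
                per_entity[kind][aspect].append(value)
    return ReadabilityResult(
        totals=totals,
        entity_counts={k: len(universe[k]) for k in ENTITY_KINDS},
        per_entity=per_entity,
        entities=universe,
    )
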