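"""Partitioning classes into top-level hierarchies and per-hierarchy pooling.

A *hierarchy* is the subtree rooted at a direct child of the ontology root
(SNOMED's 19 top-level hierarchies are the motivating instance).  Classes
with multiple parents can fall under several hierarchies; cases are
attributed to the hierarchy of the *LR class*, and an LR class that
multi-inherits into k hierarchies contributes its cases to all k rows —
double counting is made visible rather than silently resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import OntologyGraph, transitive_descendants
from .structural import MetricResult

logger = logging.getLogger(__name__)


class RootlessGraphError(Exception):
    """The root has no children; consider configuring a (virtual) root."""


@dataclass(frozen=True)
class HierarchyAssignment:
    """Map class IRI -> hierarchy IRIs (root children it descends from)."""

    assignment: dict[str, frozenset[str]]
    hierarchies: tuple[str, ...]

    def of(self, iri: str) -> frozenset[str]:
        return self.assignment.get(iri, frozenset())


def partition_by_hierarchy(graph: OntologyGraph) -> HierarchyAssignment:
    """Assign every root-reachable class to its top-level hierarchies.

    A root child is assigned to itself; the root is unassigned.
    """
    heads = graph.root_children()
    if not heads:
        raise RootlessGraphError(
            f"root {graph.root} has no children; configure a root or enable "
            "virtual-root synthesis")
    assignment: dict[str, set[str]] = {}
    for head in heads:
        for cls in transitive_descendants(graph, head) | {head}:
            assignment.setdefault(cls, set()).add(head)
    return HierarchyAssignment(
        assignment={c: frozenset(hs) for c, hs in assignment.items()},
        hierarchies=tuple(heads),
    )


def hierarchy_metrics(result: MetricResult,
                      assignment: HierarchyAssignment,
                      labels: dict[str, str] | None = None) -> pd.DataFrame:
    """Pool a metric per hierarchy, keyed by the LR class's hierarchy.

    Each row carries the LR-class count, pooled positive/negative case
    counts, the pooled value (NA when a hierarchy has LR classes but no
    cases) and summary statistics of the per-LR-class values.
    """
    per_h: dict[str, dict] = {
        h: {"n_lr_classes": 0, "n_positive": 0, "n_negative": 0, "values": []}
        for h in assignment.hierarchies}
    for report in result.reports:
        heads = assignment.of(report.lr_class.class_iri)
        if len(heads) > 1:
            logger.info("LR class %s multi-inherits into %d hierarchies; "
                        "its cases count in each", report.lr_class.class_iri,
                        len(heads))
        for head in heads:
            row = per_h[head]
            row["n_lr_classes"] += 1
            row["n_positive"] += report.n_positive
            row["n_negative"] += report.n_negative
            if report.individual_value is not None:
                row["values"].append(report.individual_value)
    rows = []
    for head in assignment.hierarchies:
        agg = per_h[head]
        total = agg["n_positive"] + agg["n_negative"]
        vals = agg["values"]
        rows.append({
            "hierarchy": head,
            "label": (labels or {}).get(head, ""),
            "n_lr_classes": agg["n_lr_classes"],
            "n_positive": agg["n_positive"],
            "n_negative": agg["n_negative"],
            "value": agg["n_positive"] / total if total else None,
            "mean_individual_value": float(np.mean(vals)) if vals else None,
            "median_individual_value": float(np.median(vals)) if vals else None,
        })
    return pd.DataFrame(rows, columns=[
        "hierarchy", "label", "n_lr_classes", "n_positive", "n_negative",
        "value", "mean_individual_value", "median_individual_value"])
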