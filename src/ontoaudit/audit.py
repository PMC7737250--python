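"""The audit driver: run every metric over one or more ontology files.

``run_audit`` is what the command-line interface wraps.  For each input it
writes a bundle of tables (readability ratios, LR-class inventory, both
structural-accuracy reports, per-hierarchy pooling, negative-case listings,
a JSON summary) plus one longitudinal CSV of the global values across all
inputs — running the tool over successive releases of an ontology yields a
trend table directly.

Outputs are deterministic: the same input and config produce byte-identical
bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import AuditConfig
from .hierarchy import RootlessGraphError, hierarchy_metrics, partition_by_hierarchy
from .io import load_ontology
from .lexreg import canonical_labels, detect_lr_classes
from .model import OntologyGraph
from .readability import ReadabilityResult, readability_metrics
from .structural import (
    NEGATIVE,
    Case,
    MetricResult,
    compute_metric,
    distance_significance_test,
)

logger = logging.getLogger(__name__)

_METRIC_KEYS = {"lsld": "lsld", "sysnaming": "systematic_naming"}


@dataclass
class AuditEntry:
    """Everything computed for a single input file."""

    path: Path
    graph: OntologyGraph
    readability: ReadabilityResult | None = None
    lr_classes: list = field(default_factory=list)
    metrics: dict[str, MetricResult] = field(default_factory=dict)
    cases: dict[str, dict[str, list[Case]]] = field(default_factory=dict)
    hierarchy_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class AuditBundle:
    entries: list[AuditEntry]
    failures: list[tuple[Path, str]]
    longitudinal: pd.DataFrame

    @property
    def ok(self) -> bool:
        return not self.failures


def audit_graph(graph: OntologyGraph, config: AuditConfig = AuditConfig(),
                path: Path = Path("<memory>")) -> AuditEntry:
    """Run the configured metrics over an already-loaded graph."""
    entry = AuditEntry(path=path, graph=graph)
    logger.info("auditing %s: %d classes, %d subclass edges, %d semantic edges",
                path, len(graph.classes), len(graph.subclass_edges),
                len(graph.semantic_edges))
    if "readability" in config.metrics:
        entry.readability = readability_metrics(graph, config.catalog)
    structural = [m for m in config.metrics if m in _METRIC_KEYS]
    if structural:
        labels = canonical_labels(graph, config.lex)
        entry.lr_classes = detect_lr_classes(graph, config.lex, labels=labels)
        logger.info("%d labelled classes, %d LR classes",
                    len(labels), len(entry.lr_classes))
        try:
            assignment = partition_by_hierarchy(graph)
        except RootlessGraphError:
            assignment = None
            logger.warning("no top-level hierarchies; per-hierarchy tables skipped")
        label_map = {c: " ".join(t) for c, t in labels.items()}
        for short in structural:
            name = _METRIC_KEYS[short]
            result, cases = compute_metric(
                graph, name, config.lex, lr_classes=entry.lr_classes,
                keep_cases=True)
            if config.wilcoxon_method != "paired":
                result.wilcoxon = distance_significance_test(
                    result.reports, method=config.wilcoxon_method)
            entry.metrics[short] = result
            entry.cases[short] = cases
            logger.info("%s: %d positive / %d negative cases, global=%s",
                        name, result.n_positive, result.n_negative,
                        result.global_value)
            if assignment is not None:
                entry.hierarchy_tables[short] = hierarchy_metrics(
                    result, assignment, labels=label_map)
    return entry


def run_audit(paths: list[str | Path], out_dir: str | Path,
              config: AuditConfig = AuditConfig(),
              fmt: str = "csv") -> AuditBundle:
    """Audit each input file and write the report bundle under ``out_dir``.

    An unparseable input is recorded as a failure and the remaining inputs
    are still processed; callers should surface a partial-failure status.
    """
    if not paths:
        raise ValueError("at least one input ontology is required")
    if fmt not in ("csv", "json"):
        raise ValueError(f"unknown output format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[AuditEntry] = []
    failures: list[tuple[Path, str]] = []
    for raw in paths:
        path = Path(raw)
        try:
            graph = load_ontology(path, root=config.root)
            entry = audit_graph(graph, config, path=path)
        except Exception as exc:
            logger.error("failed to audit %s: %s", path, exc)
            failures.append((path, str(exc)))
            continue
        entries.append(entry)
        _write_entry(entry, out_dir / path.stem, fmt)
    longitudinal = _longitudinal_frame(entries, failures)
    longitudinal.to_csv(out_dir / "longitudinal.csv", index=False)
    return AuditBundle(entries=entries, failures=failures,
                       longitudinal=longitudinal)


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------


def _write_frame(frame: pd.DataFrame, path: Path, fmt: str) -> None:
    if fmt == "csv":
        frame.to_csv(path.with_suffix(".csv"), index=False)
    else:
        frame.to_json(path.with_suffix(".json"), orient="records", indent=2)


def _write_entry(entry: AuditEntry, out_dir: Path, fmt: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if entry.readability is not None:
        _write_frame(entry.readability.to_frame(), out_dir / "readability", fmt)
    lr_rows = pd.DataFrame(
        [{"lr_class_id": lr.class_iri, "label": lr.label, "support": lr.support}
         for lr in entry.lr_classes],
        columns=["lr_class_id", "label", "support"])
    _write_frame(lr_rows, out_dir / "lr_classes", fmt)
    for short, result in entry.metrics.items():
        stem = "lsld_report" if short == "lsld" else "sysnaming_report"
        _write_frame(result.to_frame(), out_dir / stem, fmt)
        negatives = [
            {"lr_class_id": lr_iri, "subject_id": c.subject,
             "subject_label": _label_of(entry.graph, c.subject),
             "distance": c.distance}
            for lr_iri, cases in sorted(entry.cases[short].items())
            for c in cases if c.polarity == NEGATIVE]
        _write_frame(pd.DataFrame(
            negatives, columns=["lr_class_id", "subject_id", "subject_label",
                                "distance"]),
            out_dir / f"negative_cases_{short}", fmt)
    for short, table in entry.hierarchy_tables.items():
        _write_frame(table, out_dir / f"hierarchy_{short}", fmt)
    (out_dir / "summary.json").write_text(
        json.dumps(summarize(entry), indent=2, sort_keys=True) + "\n")


def _label_of(graph: OntologyGraph, iri: str) -> str:
    from .io import RDFS_LABEL

    values = graph.labels_of(iri, RDFS_LABEL)
    return values[0] if values else ""


def summarize(entry: AuditEntry) -> dict:
    """JSON-ready summary of one audited input."""
    summary: dict = {
        "input": str(entry.path),
        "n_classes": len(entry.graph.classes),
        "n_subclass_edges": len(entry.graph.subclass_edges),
        "n_lr_classes": len(entry.lr_classes),
        "distance_na_policy": "cases reachable only through non-hierarchical "
                              "edges carry NA distance and are excluded from "
                              "distance averages",
    }
    if entry.readability is not None:
        summary["readability"] = {
            f"{aspect}_per_{kind}": entry.readability.ratio(kind, aspect)
            for kind in ("class", "object_property", "datatype_property",
                         "annotation_property")
            for aspect in ("names", "synonyms", "descriptions")}
    for short, result in entry.metrics.items():
        summary[short] = {
            "global_value": result.global_value,
            "n_positive": result.n_positive,
            "n_negative": result.n_negative,
            "wilcoxon": list(result.wilcoxon),
            "spearman": list(result.spearman),
        }
    return summary


def _longitudinal_frame(entries: list[AuditEntry],
                        failures: list[tuple[Path, str]]) -> pd.DataFrame:
    rows = []
    for entry in entries:
        row: dict = {"input": str(entry.path), "status": "ok",
                     "n_classes": len(entry.graph.classes),
                     "n_lr_classes": len(entry.lr_classes)}
        if entry.readability is not None:
            for aspect in ("names", "synonyms", "descriptions"):
                row[f"{aspect}_per_class"] = entry.readability.ratio("class", aspect)
        for short, result in entry.metrics.items():
            row[f"{short}_global"] = result.global_value
        rows.append(row)
    for path, message in failures:
        rows.append({"input": str(path), "status": f"failed: {message}"})
    return pd.DataFrame(rows)
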