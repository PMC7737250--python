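"""Structural-accuracy metrics: LSLD and systematic naming.

Both metrics are anchored on LR classes (see :mod:`ontoaudit.lexreg`):

* *Lexically suggest, logically define* (LSLD): of the classes whose labels
  exhibit an LR class's regularity, the fraction that are semantically
  related to that LR class over the decomposed axiom graph.  A label that
  names a concept the axioms do not connect to is a negative case —
  content expressed for humans but missing for machines.
* *Systematic naming*: of an LR class's transitive subclass descendants,
  the fraction whose labels exhibit the regularity.  A descendant whose
  label drops the ancestor's pattern is a negative case — either the name
  or the position in the taxonomy is suspect.

The global value of either metric is micro-averaged: pooled positives over
pooled cases across all LR classes.  LR classes with many negative cases
therefore dominate it, which is the intended behaviour — the per-LR-class
distribution is carried alongside for the macro view.

Two follow-up analyses accompany each metric: a Wilcoxon signed-rank test
comparing the mean taxonomic distance of positive vs. negative cases,
paired by LR class, and a Spearman correlation between LR-class depth and
the per-LR-class metric value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .lexreg import LexConfig, LRClass, Tokens, canonical_labels, detect_lr_classes, exhibits
from .model import (
    OntologyGraph,
    all_depths,
    distances_from,
    semantic_reach,
    transitive_descendants,
)

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

MetricName = Literal["lsld", "systematic_naming"]


@dataclass(frozen=True)
class Case:
    """One evaluated (LR class, subject) pair.

    ``distance`` is the taxonomic distance between the subject and the LR
    class over is-a links only; None when the two are connected solely
    through non-hierarchical edges (such a case contributes no distance to
    the averages).
    """

    lr_class: LRClass
    subject: str
    polarity: str
    distance: int | None


@dataclass(frozen=True)
class LRClassReport:
    """Per-LR-class row: depth, case counts, case descriptors, metric value."""

    lr_class: LRClass
    depth: int | None
    n_positive: int
    mean_positive_depth: float | None
    mean_positive_distance: float | None
    n_negative: int
    mean_negative_depth: float | None
    mean_negative_distance: float | None
    individual_value: float | None


class WilcoxonResult(NamedTuple):
    statistic: float | None
    p_value: float | None
    n_pairs: int


class SpearmanResult(NamedTuple):
    rho: float | None
    p_value: float | None
    n: int


@dataclass
class MetricResult:
    metric: str
    global_value: float | None
    n_positive: int
    n_negative: int
    reports: list[LRClassReport]
    wilcoxon: WilcoxonResult
    spearman: SpearmanResult

    @property
    def n_cases(self) -> int:
        return self.n_positive + self.n_negative

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            rows.append({
                "lr_class_id": r.lr_class.class_iri,
                "label": r.lr_class.label,
                "depth": r.depth,
                "n_positive": r.n_positive,
                "mean_pos_depth": r.mean_positive_depth,
                "mean_pos_distance": r.mean_positive_distance,
                "n_negative": r.n_negative,
                "mean_neg_depth": r.mean_negative_depth,
                "mean_neg_distance": r.mean_negative_distance,
                "value": r.individual_value,
            })
        return pd.DataFrame(rows, columns=[
            "lr_class_id", "label", "depth", "n_positive", "mean_pos_depth",
            "mean_pos_distance", "n_negative", "mean_neg_depth",
            "mean_neg_distance", "value"])


# --------------------------------------------------------------------------
# case construction
# --------------------------------------------------------------------------


def lsld_cases(graph: OntologyGraph, lr: LRClass,
               cfg: LexConfig = LexConfig(),
               labels: dict[str, Tokens] | None = None) -> list[Case]:
    """LSLD cases for one LR class.

    One case per class whose label exhibits the regularity, excluding every
    class whose full label *equals* it (the LR class itself and any
    duplicate-labelled twin).  Positive iff the subject is semantically
    related to the LR class.
    """
    if labels is None:
        labels = canonical_labels(graph, cfg)
    forward, backward = semantic_reach(graph, lr.class_iri)
    related = forward | backward
    dist = distances_from(graph, lr.class_iri)
    cases = []
    for subject in sorted(labels):
        tokens = labels[subject]
        if tokens == lr.regularity:
            continue
        if not exhibits(tokens, lr.regularity):
            continue
        polarity = POSITIVE if subject in related else NEGATIVE
        cases.append(Case(lr, subject, polarity, dist.get(subject)))
    return cases


def systematic_naming_cases(graph: OntologyGraph, lr: LRClass,
                            cfg: LexConfig = LexConfig(),
                            labels: dict[str, Tokens] | None = None) -> list[Case]:
    """Systematic-naming cases: one per transitive descendant of the LR class.

    Positive iff the descendant's label exhibits the regularity; a
    descendant without a usable label cannot exhibit it and is negative.
    Leaf LR classes yield the empty list (their value is NA).
    """
    if labels is None:
        labels = canonical_labels(graph, cfg)
    dist = distances_from(graph, lr.class_iri)
    cases = []
    for subject in sorted(transitive_descendants(graph, lr.class_iri)):
        tokens = labels.get(subject)
        hit = tokens is not None and exhibits(tokens, lr.regularity)
        cases.append(Case(lr, subject, POSITIVE if hit else NEGATIVE,
                          dist.get(subject)))
    return cases


def _mean(values: Iterable[float]) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def build_report(graph: OntologyGraph, lr: LRClass, cases: list[Case],
                 depths: dict[str, int] | None = None) -> LRClassReport:
    """Summarize one LR class's case list into a report row.

    NA distances are dropped from the means; an all-NA case set yields an
    NA mean, never zero.
    """
    if depths is None:
        depths = all_depths(graph)
    pos = [c for c in cases if c.polarity == POSITIVE]
    neg = [c for c in cases if c.polarity == NEGATIVE]
    total = len(pos) + len(neg)
    return LRClassReport(
        lr_class=lr,
        depth=depths.get(lr.class_iri),
        n_positive=len(pos),
        mean_positive_depth=_mean(depths.get(c.subject) for c in pos),
        mean_positive_distance=_mean(c.distance for c in pos),
        n_negative=len(neg),
        mean_negative_depth=_mean(depths.get(c.subject) for c in neg),
        mean_negative_distance=_mean(c.distance for c in neg),
        individual_value=len(pos) / total if total else None,
    )


# --------------------------------------------------------------------------
# metric computation
# --------------------------------------------------------------------------

_CASE_BUILDERS = {
    "lsld": lsld_cases,
    "systematic_naming": systematic_naming_cases,
}


def compute_metric(graph: OntologyGraph, metric: MetricName,
                   cfg: LexConfig = LexConfig(),
                   lr_classes: list[LRClass] | None = None,
                   keep_cases: bool = False,
                   ) -> MetricResult | tuple[MetricResult, dict[str, list[Case]]]:
    """Detect LR classes, build every case list and pool the metric.

    LR classes are processed in lexicographic IRI order so outputs are
    byte-stable.  With ``keep_cases`` the per-LR-class case lists are
    returned alongside (for negative-case listings).
    """
    if metric not in _CASE_BUILDERS:
        raise ValueError(f"unknown metric {metric!r}")
    labels = canonical_labels(graph, cfg)
    if lr_classes is None:
        lr_classes = detect_lr_classes(graph, cfg, labels=labels)
    depths = all_depths(graph)
    builder = _CASE_BUILDERS[metric]
    reports: list[LRClassReport] = []
    all_cases: dict[str, list[Case]] = {}
    n_pos = n_neg = 0
    for lr in lr_classes:
        cases = builder(graph, lr, cfg, labels=labels)
        reports.append(build_report(graph, lr, cases, depths))
        n_pos += sum(1 for c in cases if c.polarity == POSITIVE)
        n_neg += sum(1 for c in cases if c.polarity == NEGATIVE)
        if keep_cases:
            all_cases[lr.class_iri] = cases
    total = n_pos + n_neg
    result = MetricResult(
        metric=metric,
        global_value=n_pos / total if total else None,
        n_positive=n_pos,
        n_negative=n_neg,
        reports=reports,
        wilcoxon=distance_significance_test(reports),
        spearman=depth_metric_correlation(reports),
    )
    if not lr_classes:
        logger.warning("no LR classes detected; %s metric is NA", metric)
    return (result, all_cases) if keep_cases else result


# --------------------------------------------------------------------------
# follow-up statistics
# --------------------------------------------------------------------------


def distance_significance_test(reports: list[LRClassReport],
                               method: str = "paired") -> WilcoxonResult:
    """Do negative cases sit farther from their LR class than positive ones?

    ``paired`` (default) runs a two-sided Wilcoxon signed-rank over the
    (mean positive distance, mean negative distance) pairs of the reports
    where both are defined.  ``unpaired`` runs a two-sided Mann-Whitney
    rank-sum over the two pools of defined means instead.  Returns an NA
    triple when fewer than two usable observations exist.
    """
    if method == "paired":
        pairs = [(r.mean_positive_distance, r.mean_negative_distance)
                 for r in reports
                 if r.mean_positive_distance is not None
                 and r.mean_negative_distance is not None]
        if len(pairs) < 2:
            logger.warning("distance test undersized: %d pair(s)", len(pairs))
            return WilcoxonResult(None, None, len(pairs))
        pos, neg = map(np.asarray, zip(*pairs))
        if np.all(pos == neg):
            return WilcoxonResult(0.0, 1.0, len(pairs))
        res = stats.wilcoxon(pos, neg, alternative="two-sided")
        return WilcoxonResult(float(res.statistic), float(res.pvalue), len(pairs))
    if method == "unpaired":
        pos = [r.mean_positive_distance for r in reports
               if r.mean_positive_distance is not None]
        neg = [r.mean_negative_distance for r in reports
               if r.mean_negative_distance is not None]
        if len(pos) < 1 or len(neg) < 1 or len(pos) + len(neg) < 2:
            return WilcoxonResult(None, None, min(len(pos), len(neg)))
        res = stats.mannwhitneyu(pos, neg, alternative="two-sided")
        return WilcoxonResult(float(res.statistic), float(res.pvalue),
                              min(len(pos), len(neg)))
    raise ValueError(f"unknown method {method!r}")


def depth_metric_correlation(reports: list[LRClassReport]) -> SpearmanResult:
    """Spearman rank correlation between LR-class depth and metric value.

    Uses the reports where both depth and individual value are defined;
    NA when fewer than three remain or either variable is constant.
    """
    points = [(r.depth, r.individual_value) for r in reports
              if r.depth is not None and r.individual_value is not None]
    n = len(points)
    if n < 3:
        return SpearmanResult(None, None, n)
    depths, values = map(np.asarray, zip(*points))
    if np.all(depths == depths[0]) or np.all(values == values[0]):
        return SpearmanResult(None, None, n)
    rho, p = stats.spearmanr(depths, values)
    if np.isnan(rho):
        return SpearmanResult(None, None, n)
    return SpearmanResult(float(rho), float(p), n)
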