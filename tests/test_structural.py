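"""LSLD and systematic-naming metrics, reports and follow-up statistics."""

import numpy as np
import pytest

from ontoaudit import (
    LexConfig,
    compute_metric,
    depth_metric_correlation,
    detect_lr_classes,
    distance_significance_test,
    lsld_cases,
    systematic_naming_cases,
)
from ontoaudit.fixtures import SynthSpec, generate_synthetic_ontology
from ontoaudit.lexreg import LRClass
from ontoaudit.model import OntologyGraph
from ontoaudit.structural import NEGATIVE, POSITIVE, LRClassReport

from conftest import f1, oracle_descendants, oracle_exhibits, oracle_related


def lr_by_label(graph, label):
    for lr in detect_lr_classes(graph):
        if lr.label == label:
            return lr
    raise AssertionError(f"no LR class labelled {label!r}")


class TestWorkedExample:
    def test_lsld_cases_for_procedure(self, fig1):
        cases = lsld_cases(fig1, lr_by_label(fig1, "procedure"))
        polarity = {c.subject: c.polarity for c in cases}
        assert polarity == {
            f1("AdministrativeProcedure"): POSITIVE,
            f1("DeathAdministrativeProcedure"): POSITIVE,
            f1("CosmeticProcedure"): NEGATIVE,
        }

    def test_lsld_global_is_three_quarters(self, fig1):
        result = compute_metric(fig1, "lsld")
        assert result.global_value == pytest.approx(0.75)
        assert (result.n_positive, result.n_negative) == (3, 1)

    def test_sysnaming_cases_for_procedure(self, fig1):
        cases = systematic_naming_cases(fig1, lr_by_label(fig1, "procedure"))
        polarity = {c.subject: c.polarity for c in cases}
        assert polarity == {
            f1("AdministrativeProcedure"): POSITIVE,
            f1("DeathAdministrativeProcedure"): POSITIVE,
            f1("BiopsyAdministration"): NEGATIVE,
        }

    def test_sysnaming_global_is_three_fifths(self, fig1):
        result = compute_metric(fig1, "systematic_naming")
        assert result.global_value == pytest.approx(0.6)
        values = {r.lr_class.label: r.individual_value for r in result.reports}
        assert values["procedure"] == pytest.approx(2 / 3)
        assert values["administrative procedure"] == pytest.approx(1 / 2)

    def test_case_distances(self, fig1):
        cases = lsld_cases(fig1, lr_by_label(fig1, "procedure"))
        dist = {c.subject: c.distance for c in cases}
        assert dist[f1("AdministrativeProcedure")] == 1
        assert dist[f1("DeathAdministrativeProcedure")] == 2
        assert dist[f1("CosmeticProcedure")] == 2  # via the root


def test_leaf_lr_class_has_na_individual_value():
    g = OntologyGraph(root="urn:t:root")
    g.add_class("urn:t:root", "root")
    g.add_class("urn:t:a", "shunt")
    g.add_class("urn:t:b", "cardiac shunt")
    g.add_subclass_of("urn:t:a", "urn:t:root")
    g.add_subclass_of("urn:t:b", "urn:t:root")  # sibling, not descendant
    result = compute_metric(g, "systematic_naming")
    report = {r.lr_class.label: r for r in result.reports}["shunt"]
    assert report.n_positive == report.n_negative == 0
    assert report.individual_value is None
    assert report.mean_positive_distance is None


def test_lr_with_no_exhibiting_classes_is_impossible_by_detection(fig1):
    # hand-built LR with an alien regularity: empty case list, NA value
    lr = LRClass(f1("Procedure"), ("zebra",), 0)
    assert lsld_cases(fig1, lr) == []


def test_fully_compliant_chain_scores_one():
    g = OntologyGraph(root="urn:t:root")
    g.add_class("urn:t:root", "root")
    g.add_class("urn:t:a", "wound")
    g.add_class("urn:t:b", "open wound")
    g.add_class("urn:t:c", "infected open wound")
    g.add_subclass_of("urn:t:a", "urn:t:root")
    g.add_subclass_of("urn:t:b", "urn:t:a")
    g.add_subclass_of("urn:t:c", "urn:t:b")
    for metric in ("lsld", "systematic_naming"):
        assert compute_metric(g, metric).global_value == 1.0


def test_pooling_identity_and_micro_vs_macro():
    g, _ = generate_synthetic_ontology(
        SynthSpec(n_classes=800, p_name_inherit=0.5, p_axiom_link=0.3, seed=3))
    result = compute_metric(g, "systematic_naming")
    # pooled identity holds in exact integer arithmetic
    assert result.global_value * result.n_cases == pytest.approx(
        result.n_positive, abs=1e-9)
    macro = np.mean([r.individual_value for r in result.reports
                     if r.individual_value is not None])
    assert result.global_value != pytest.approx(float(macro), abs=1e-6)


def test_duplicate_label_lr_classes_each_get_their_own_cases():
    g = OntologyGraph(root="urn:t:root")
    g.add_class("urn:t:root", "root")
    g.add_class("urn:t:d1", "open wound")   # disorder sense
    g.add_class("urn:t:d2", "open wound")   # morphology sense
    g.add_class("urn:t:s", "large open wound")
    g.add_subclass_of("urn:t:d1", "urn:t:root")
    g.add_subclass_of("urn:t:d2", "urn:t:root")
    g.add_subclass_of("urn:t:s", "urn:t:d1")
    result = compute_metric(g, "lsld")
    # the exhibiting class is a case against EACH duplicate LR class,
    # positive only where a semantic path exists
    by_iri = {r.lr_class.class_iri: r for r in result.reports}
    assert by_iri["urn:t:d1"].n_positive == 1
    assert by_iri["urn:t:d2"].n_negative == 1
    assert result.n_cases == 2


def test_renaming_negative_case_flips_exactly_that_case(fig1):
    g = OntologyGraph(
        classes=set(fig1.classes),
        annotations={e: set(v) for e, v in fig1.annotations.items()},
        subclass_edges=set(fig1.subclass_edges),
        semantic_edges=dict(fig1.semantic_edges),
        root=fig1.root)
    g.annotations[f1("BiopsyAdministration")] = set()
    g.add_annotation(f1("BiopsyAdministration"),
                     "http://www.w3.org/2000/01/rdf-schema#label",
                     "Biopsy administrative procedure")
    before = compute_metric(fig1, "systematic_naming")
    after = compute_metric(g, "systematic_naming")
    assert after.n_positive == before.n_positive + 2  # one case per ancestor LR
    assert after.n_negative == before.n_negative - 2
    assert after.global_value == 1.0


def test_removing_semantic_edge_never_raises_lsld(fig1):
    g = OntologyGraph(
        classes=set(fig1.classes),
        annotations={e: set(v) for e, v in fig1.annotations.items()},
        subclass_edges=set(fig1.subclass_edges),
        semantic_edges=dict(fig1.semantic_edges),
        root=fig1.root)
    del g.semantic_edges[(f1("DeathAdministrativeProcedure"),
                          f1("AdministrativeProcedure"))]
    weakened = compute_metric(g, "lsld").global_value
    assert weakened <= compute_metric(fig1, "lsld").global_value


@pytest.mark.parametrize("seed", range(6))
def test_case_polarities_agree_with_first_principles(seed):
    """Both metrics recomputed via closure matrices and string containment."""
    g = random_ontology_with_labels(seed)
    labels = {}
    from ontoaudit.lexreg import canonical_labels

    labels = canonical_labels(g)
    for lr in detect_lr_classes(g):
        for case in lsld_cases(g, lr):
            assert (case.polarity == POSITIVE) == oracle_related(
                g, case.subject, lr.class_iri)
        for case in systematic_naming_cases(g, lr):
            assert case.subject in oracle_descendants(g, lr.class_iri)
            expected = oracle_exhibits(labels[case.subject], lr.regularity)
            assert (case.polarity == POSITIVE) == expected


def random_ontology_with_labels(seed):
    from ontoaudit import random_ontology

    return random_ontology(35, seed=seed)


class TestDistanceSignificance:
    @staticmethod
    def report(pos_dist, neg_dist, depth=3, value=0.5):
        lr = LRClass("urn:t:x", ("x",), 1)
        return LRClassReport(lr, depth, 1, None, pos_dist, 1, None, neg_dist, value)

    def test_identical_pairs_yield_null_p(self):
        reports = [self.report(2.0, 2.0) for _ in range(10)]
        stat, p, n = distance_significance_test(reports)
        assert n == 10
        assert p == pytest.approx(1.0)

    def test_planted_shift_detected_and_matches_permutation_oracle(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(1, 3, size=60)
        neg = pos + 1.0 + rng.normal(0, 0.2, size=60)
        reports = [self.report(p_, n_) for p_, n_ in zip(pos, neg)]
        stat, p, n = distance_significance_test(reports)
        assert p < 0.05
        # sign-flip permutation oracle on the paired differences
        diffs = neg - pos
        observed = abs(diffs.mean())
        flips = rng.choice([-1.0, 1.0], size=(2000, diffs.size))
        perm = np.abs((flips * diffs).mean(axis=1))
        p_perm = (np.sum(perm >= observed) + 1) / (flips.shape[0] + 1)
        assert p_perm < 0.05

    def test_single_pair_is_na(self):
        reports = [self.report(1.0, 2.0), self.report(None, 2.0)]
        stat, p, n = distance_significance_test(reports)
        assert (stat, p, n) == (None, None, 1)

    def test_unpaired_variant_runs(self):
        reports = [self.report(1.0, None) for _ in range(5)] + \
                  [self.report(None, 3.0) for _ in range(5)]
        stat, p, n = distance_significance_test(reports, method="unpaired")
        assert p is not None and p < 0.05


class TestDepthCorrelation:
    @staticmethod
    def report(depth, value):
        lr = LRClass(f"urn:t:{depth}-{value}", ("x",), 1)
        return LRClassReport(lr, depth, 1, None, None, 1, None, None, value)

    def test_perfect_monotone_gives_rho_one(self):
        reports = [self.report(d, d / 10) for d in range(1, 8)]
        rho, p, n = depth_metric_correlation(reports)
        assert rho == pytest.approx(1.0)
        assert n == 7

    def test_constant_values_are_na(self):
        reports = [self.report(d, 0.5) for d in range(1, 8)]
        assert depth_metric_correlation(reports) == (None, None, 7)

    def test_fewer_than_three_points_is_na(self):
        reports = [self.report(1, 0.1), self.report(2, 0.2),
                   self.report(None, 0.3)]
        assert depth_metric_correlation(reports) == (None, None, 2)

    def test_independent_values_near_zero_rho(self):
        rng = np.random.default_rng(1)
        reports = [self.report(int(d), float(v))
                   for d, v in zip(rng.integers(1, 12, 200), rng.uniform(0, 1, 200))]
        rho, p, n = depth_metric_correlation(reports)
        assert abs(rho) < 0.15
        assert p > 0.05
        # exact-rank oracle: scipy-free Spearman via rank Pearson
        depths = np.array([r.depth for r in reports], dtype=float)
        values = np.array([r.individual_value for r in reports])
        rd = rank(depths)
        rv = rank(values)
        rho_oracle = np.corrcoef(rd, rv)[0, 1]
        assert rho == pytest.approx(rho_oracle, abs=1e-10)


def rank(x):
    """Average ranks, computed directly from argsort runs."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks
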