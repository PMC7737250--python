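"""Top-level hierarchy partitioning, per-hierarchy pooling, audit driver."""

import json

import pytest

from ontoaudit import (
    AuditConfig,
    compute_metric,
    hierarchy_metrics,
    partition_by_hierarchy,
    run_audit,
    to_rdfxml,
)
from ontoaudit.fixtures import SynthSpec, generate_synthetic_ontology
from ontoaudit.hierarchy import RootlessGraphError
from ontoaudit.model import OntologyGraph

from conftest import f1


class TestPartition:
    def test_worked_example_partition(self, fig1):
        assignment = partition_by_hierarchy(fig1)
        assert set(assignment.hierarchies) == {
            f1("Procedure"), f1("CosmeticProcedure")}
        assert assignment.of(f1("DeathAdministrativeProcedure")) == {
            f1("Procedure")}
        # a root child is assigned to itself; the root is unassigned
        assert assignment.of(f1("CosmeticProcedure")) == {f1("CosmeticProcedure")}
        assert assignment.of(fig1.root) == frozenset()

    def test_multi_inheriting_class_lands_in_both(self):
        g = OntologyGraph(root="urn:t:root")
        for n in ("root", "h1", "h2", "x"):
            g.add_class(f"urn:t:{n}")
        g.add_subclass_of("urn:t:h1", "urn:t:root")
        g.add_subclass_of("urn:t:h2", "urn:t:root")
        g.add_subclass_of("urn:t:x", "urn:t:h1")
        g.add_subclass_of("urn:t:x", "urn:t:h2")
        assignment = partition_by_hierarchy(g)
        assert assignment.of("urn:t:x") == {"urn:t:h1", "urn:t:h2"}

    def test_rootless_graph_raises(self):
        g = OntologyGraph(root="urn:t:lonely")
        g.add_class("urn:t:lonely")
        with pytest.raises(RootlessGraphError):
            partition_by_hierarchy(g)


class TestHierarchyMetrics:
    def test_single_hierarchy_row_equals_global(self, fig1):
        result = compute_metric(fig1, "systematic_naming")
        table = hierarchy_metrics(result, partition_by_hierarchy(fig1))
        rows = table.set_index("hierarchy")
        proc = rows.loc[f1("Procedure")]
        assert proc["n_lr_classes"] == 2
        assert proc["value"] == pytest.approx(result.global_value)
        cosmetic = rows.loc[f1("CosmeticProcedure")]
        assert cosmetic["n_lr_classes"] == 0

    def test_hierarchy_with_lr_classes_but_no_cases_is_na(self):
        g = OntologyGraph(root="urn:t:root")
        g.add_class("urn:t:root", "root")
        g.add_class("urn:t:h", "alpha")
        g.add_class("urn:t:leaf", "shunt")
        g.add_class("urn:t:other", "cardiac shunt")
        g.add_subclass_of("urn:t:h", "urn:t:root")
        g.add_subclass_of("urn:t:leaf", "urn:t:h")
        g.add_class("urn:t:h2", "beta")
        g.add_subclass_of("urn:t:h2", "urn:t:root")
        g.add_subclass_of("urn:t:other", "urn:t:h2")
        result = compute_metric(g, "systematic_naming")
        table = hierarchy_metrics(result, partition_by_hierarchy(g))
        row = table.set_index("hierarchy").loc["urn:t:h"]
        assert row["n_lr_classes"] == 1  # the leaf LR class "shunt"
        assert row["value"] is None or row["value"] != row["value"]  # NA

    def test_per_hierarchy_counts_sum_to_global_without_multi_inheritance(self):
        g, _ = generate_synthetic_ontology(
            SynthSpec(n_classes=700, n_hierarchies=3, seed=9))
        result = compute_metric(g, "systematic_naming")
        table = hierarchy_metrics(result, partition_by_hierarchy(g))
        assert table["n_positive"].sum() == result.n_positive
        assert table["n_negative"].sum() == result.n_negative
        assert table["n_lr_classes"].sum() == len(result.reports)

    def test_planted_per_hierarchy_compliance_recovered(self):
        g, truth = generate_synthetic_ontology(SynthSpec(
            n_classes=2200, n_hierarchies=2, p_name_inherit=(0.9, 0.2),
            p_axiom_link=0.5, seed=17))
        result = compute_metric(g, "systematic_naming")
        table = hierarchy_metrics(result, partition_by_hierarchy(g))
        rows = table.set_index("hierarchy")
        for head, planted in (("urn:synth:h0", 0.9), ("urn:synth:h1", 0.2)):
            row = rows.loc[head]
            n = row["n_positive"] + row["n_negative"]
            se = (planted * (1 - planted) / n) ** 0.5
            assert abs(row["value"] - planted) < 3 * se + 1e-9


class TestRunAudit:
    def test_bundle_on_worked_example(self, fig1, tmp_path):
        src = tmp_path / "fig1.owl"
        to_rdfxml(fig1, src)
        bundle = run_audit([src], tmp_path / "out")
        assert bundle.ok
        summary = json.loads((tmp_path / "out" / "fig1" / "summary.json").read_text())
        assert summary["sysnaming"]["global_value"] == pytest.approx(0.6)
        assert summary["lsld"]["global_value"] == pytest.approx(0.75)
        assert summary["n_lr_classes"] == 2
        for name in ("readability.csv", "lr_classes.csv", "lsld_report.csv",
                     "sysnaming_report.csv", "hierarchy_lsld.csv",
                     "hierarchy_sysnaming.csv", "negative_cases_lsld.csv",
                     "negative_cases_sysnaming.csv", "summary.json"):
            assert (tmp_path / "out" / "fig1" / name).exists()
        assert (tmp_path / "out" / "longitudinal.csv").exists()

    def test_repeat_runs_are_byte_identical(self, fig1, tmp_path):
        src = tmp_path / "fig1.owl"
        to_rdfxml(fig1, src)
        run_audit([src], tmp_path / "a")
        run_audit([src], tmp_path / "b")
        for name in ("fig1/summary.json", "fig1/sysnaming_report.csv",
                     "fig1/negative_cases_lsld.csv", "longitudinal.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_two_copies_give_identical_longitudinal_rows(self, fig1, tmp_path):
        a, b = tmp_path / "v1.owl", tmp_path / "v2.owl"
        to_rdfxml(fig1, a)
        to_rdfxml(fig1, b)
        bundle = run_audit([a, b], tmp_path / "out")
        frame = bundle.longitudinal.drop(columns="input")
        assert frame.iloc[0].equals(frame.iloc[1])

    def test_bad_input_recorded_and_rest_processed(self, fig1, tmp_path):
        good = tmp_path / "fig1.owl"
        to_rdfxml(fig1, good)
        bad = tmp_path / "broken.owl"
        bad.write_text("<not xml")
        bundle = run_audit([bad, good], tmp_path / "out")
        assert not bundle.ok
        assert len(bundle.entries) == 1
        assert len(bundle.failures) == 1
        statuses = set(bundle.longitudinal["status"])
        assert "ok" in statuses and any(s.startswith("failed") for s in statuses)

    def test_empty_input_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            run_audit([], tmp_path / "out")
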