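"""The six-class worked example: detect LR classes and compute both metrics.

The fixture is a small procedure taxonomy: Procedure and Cosmetic procedure
under the root, Administrative procedure under Procedure, and Death
administrative procedure / Biopsy administration under that.  Two labels
recur inside other labels, so there are two LR classes, and every metric
value can be verified by hand.
"""

from ontoaudit import compute_metric, detect_lr_classes, figure1_ontology

g = figure1_ontology()
print(f"classes: {len(g.classes)}, subclass edges: {len(g.subclass_edges)}")

for lr in detect_lr_classes(g):
    print(f"LR class {lr.label!r}: exhibited by {lr.support} other class(es)")

lsld = compute_metric(g, "lsld")
print(f"LSLD global value: {lsld.global_value:.3f} "
      f"({lsld.n_positive} positive / {lsld.n_negative} negative)")
# 3/4: of the four classes lexically pointing at an LR class, three are
# also reachable in the axiom graph; Cosmetic procedure is not.

sysnaming = compute_metric(g, "systematic_naming")
print(f"systematic naming global value: {sysnaming.global_value:.3f} "
      f"({sysnaming.n_positive} positive / {sysnaming.n_negative} negative)")
for report in sysnaming.reports:
    print(f"  {report.lr_class.label!r}: value="
          f"{report.individual_value:.3f} over "
          f"{report.n_positive + report.n_negative} descendants")
# 3/5 pooled: Biopsy administration breaks the naming pattern under both
# Procedure (2/3) and Administrative procedure (1/2).
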