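# Methods

This note documents the model behind each metric, the tunable parameters,
the numerical and design choices made where the design was genuinely open,
what the synthetic generator does and does not emulate, and known
limitations.

## Ontology model

An ontology is reduced to: entity sets (classes and the three property
kinds), an annotation multimap (deduplicated `(property, literal, language)`
triples per entity), and two directed edge sets over named classes.

- **Subclass edges** are asserted `rdfs:subClassOf` between named classes,
  child → parent. They carry the taxonomy: descendants, depth and
  taxonomic distance are defined on them alone.
- **Semantic edges** decompose every `owl:subClassOf` and
  `owl:equivalentClass` axiom. For `A ⊑ E` or `A ≡ E`, every named class in
  `E` — conjuncts of intersections and fillers of existential restrictions,
  at any nesting depth — yields an edge from `A`, tagged *non-hierarchical*
  when reached through a restriction and *hierarchical* otherwise.
  Equivalences additionally yield the reverse edges.

*Semantically related* means a directed path exists over semantic edges in
either orientation. Directionality is essential: an undirected search would
connect nearly everything through the root and the metric would saturate.
No reasoner is invoked; the ontology is consumed as given (pre-classified
inputs are therefore analysed post-classification).

**Depth** is the shortest subclass path from a class up to the root (NA if
detached). **Taxonomic distance** is the shortest path following is-a links
with either orientation allowed per step, so ancestor–descendant and
common-ancestor paths both count (NA when no is-a path exists). Under
multiple inheritance the shortest path wins; only lengths are reported, so
no tie-breaking is needed.

**Root resolution.** `owl:Thing` is the root when it has asserted children.
Otherwise, if exactly one class has no named superclass it becomes the root
(this keeps a fixture with an explicit top class behaving identically when
loaded from file); with several orphans a virtual root is synthesized over
all of them so depth stays defined. A config root overrides everything.

## Readability

Counts are per deduplicated assertion: serialization duplicates (same
entity, property, literal, language) count once; language-tagged variants
of one string are distinct content and count separately. Built-in
vocabulary (owl:Thing, the catalog properties themselves, a virtual root)
is excluded from denominators — it is not domain content. A kind with an
empty denominator reports NA, distinct from a zero ratio.

## Lexical regularities

Tokenization: optional removal of one trailing parenthesized semantic tag,
case folding (default insensitive), split on the blank delimiter, empty
tokens dropped. Punctuation stays inside tokens — the delimiter is the only
normalization performed. Exhibiting is exact contiguous containment of
whole tokens; gapped matches are false negatives by design (see
Limitations).

Candidate patterns are exactly the full class labels: both structural
metrics consume only the regularities of LR classes, so general frequent-
pattern mining would compute support for patterns that can never anchor a
case. Support for label `L` counts classes exhibiting `L` excluding every
class labelled exactly `L` (an LR class does not support itself, nor does a
duplicate-labelled twin). Duplicate labels produce one LR-class record per
owner class, sharing the regularity; each exhibiting class is then a case
against *each* of them, positive only where that particular pair is
related.

**Coverage** defaults to 0.001 (0.1% of classes). It is a fraction, not a
percent: at terminology scale the informative regularities sit at
sub-percent support, and a 10% threshold would leave essentially no LR
classes. This is the single most consequential dial and is surfaced in
config and CLI. Stopword-like single-token regularities ("in", "with",
numbers) are deliberately not filtered; they carry signal about how general
vocabulary is axiomatized, and filtering them is a presentation decision
left to the reader of the reports.

## Structural accuracy

Global values are micro-averaged: pooled positives over pooled cases. The
macro view (mean/median of per-LR-class values) is reported alongside in
the per-hierarchy tables; the two deliberately diverge when a few LR
classes carry very many negative cases.

Case distances come from is-a links only. A case connected to its LR class
solely through non-hierarchical edges has distance NA and is excluded from
distance means; an all-NA case set yields an NA mean, never 0, because a
zero would bias the distance test. (A consequence: mean positive distances
are always ≥ 1 here; sub-unit means would require counting restriction
edges in distances, which mixes edge semantics and is not done.)

**Distance test.** Wilcoxon signed-rank, two-sided, over
(mean positive distance, mean negative distance) pairs of the reports where
both are defined — pairing by LR class matches the per-LR-class structure
of the reports. The alternative reading, an unpaired rank-sum over the two
pools of means, is available as `wilcoxon_method: unpaired`. Fewer than two
usable pairs → NA; all-zero differences → statistic 0, p = 1 (scipy rejects
this case, so it is short-circuited).

**Depth correlation.** Spearman rank correlation between LR-class depth and
individual value over reports with both defined; NA below three points or
under zero variance in either variable.

Iteration over LR classes is in lexicographic IRI order everywhere, so
reports, bundles and logs are byte-stable across runs.

## Per-hierarchy analysis

A hierarchy is the subtree of a direct child of the root. Cases are
attributed to the hierarchy of the **LR class** (not the subject). An LR
class multi-inheriting into k hierarchies contributes its cases to all k
rows with a logged note — the double counting is made visible rather than
silently resolved, since no principled attribution exists.

## Synthetic generator

Layout: root → `n_hierarchies` heads → anchor classes with unique
single-token labels → per anchor, a Poisson(`mean_children`) set of
children and a fixed set of lexical cousins placed under a *different*
head. Children extend the anchor label with a fresh token with probability
`p_name_inherit` (per-hierarchy rates accepted); cousins always contain the
anchor label and receive an existential-restriction link to the anchor with
probability `p_axiom_link`. All other labels are built from fresh,
never-reused tokens, so exhibiting is controlled exactly and the ground
truth is exact rather than probabilistic. Annotations are planted at
Poisson rates per entity on top of the one canonical `rdfs:label`.
Generation is a pure function of the spec (seed included); one local
`numpy` generator is used, never global state.

Defaults: 2000 classes, 2 hierarchies, 8 children and 4 cousins per anchor,
inheritance and link rates 0.5, annotation rates (1.0, 0.5, 0.1) — sized so
that metric estimates carry on the order of a thousand cases while a full
pipeline run stays around a second. The anchors are the LR classes
*provided* the detection threshold does not exceed the cousin count; with
default coverage 0.001 that holds up to ~4000 classes, and the recovery
experiments stay within that regime (3400 classes, ≥ 2000 cases — large
enough that 3 binomial standard errors are a ±3-point window).

What the generator does **not** emulate: synonym-mediated regularities,
hyponymy (real negative cases are often semantically fine, e.g.
"Osteotomy" under "Incision"), shared tokens between unrelated labels,
multilingual labels, deep nesting below anchors, or description-logic
profiles beyond subclass + existential restriction. Passing recovery tests
therefore shows the estimators are unbiased under controlled compliance,
not that real-ontology values are "correct" — on real data the metrics are
descriptive, and their negative-case listings require expert review.

The statistical-test calibration (planted +1 shift; 1000-run null at
nominal 5%) uses simulated report sets directly, since only the test's
inputs matter for its size and power.

## Limitations

- Exact contiguous matching under-counts exhibiting (no gapped or inflected
  matches); lemmatization would change LR inventories.
- LSLD treats any directed semantic path as "related", regardless of
  length or property semantics.
- Very general LR classes (stopwords, numbers, upper-level concepts)
  legitimately accumulate negative cases; low values need interpretation,
  not automatic repair.
- The functional-syntax reader covers declarations, SubClassOf,
  EquivalentClasses, AnnotationAssertion, ObjectIntersectionOf and
  ObjectSomeValuesFrom; other axiom types are skipped (they do not feed any
  metric). RDF/XML via rdflib has no such restriction.
- The RDF/XML writer re-expresses non-hierarchical edges as existential
  restrictions over a single synthetic property; round-trips are exact for
  generated fixtures but lossy for ontologies with richer anonymous
  expressions.
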