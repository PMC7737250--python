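# ontoaudit

Quality-assurance metrics for OWL ontologies, aimed at curators and
knowledge engineers of large biomedical terminologies (SNOMED CT-scale
resources and smaller): **readability** — how much human-oriented content
(names, synonyms, descriptions) the entities carry — and **structural
accuracy** — how well the content written for humans in class labels agrees
with the content written for machines in axioms.

## The metrics

**Readability.** Twelve ratios: total names / synonyms / descriptions over
the number of entities, for each of classes, object properties, datatype
properties and annotation properties. Which annotation property counts as
which aspect is set by a curated catalog (skos:prefLabel, rdfs:label,
schema.org/name, … for names; skos:altLabel, oboInOwl synonyms, … for
synonyms; IAO definition, rdfs:comment, … for descriptions), overridable in
config. An absent entity kind yields NA, never 0.

**Lexical regularities.** A token pattern recurring across class labels is a
*lexical regularity* (LR); a class whose full normalized label is such a
pattern is an *LR class*. Detection is anchored on full labels with a
coverage threshold: pattern `L` qualifies when at least
`ceil(coverage · |classes|)` classes (excluding those labelled exactly `L`)
exhibit `L` as a contiguous run of whole tokens. Default coverage is 0.001.

**Structural accuracy**, two ratios pooled over all LR classes
(positives / all cases):

- *Lexically suggest, logically define (LSLD).* For each class whose label
  exhibits an LR class's regularity: positive iff a directed path connects
  it with the LR class, in either orientation, over the axiom graph —
  `owl:subClassOf` and `owl:equivalentClass` axioms decomposed into edges,
  including edges through existential restriction fillers (so
  `Structure of left upper limb ≡ … ⊓ ∃hasLaterality.Left` relates the
  class to `Left`).
- *Systematic naming.* For each transitive descendant of an LR class:
  positive iff the descendant's label exhibits the regularity.

Each LR class also gets a report row (depth, positive/negative counts, mean
case depths and taxonomic distances, individual value), and two follow-up
tests run per metric: a Wilcoxon signed-rank comparing positive vs negative
mean distances paired by LR class, and a Spearman correlation between LR
class depth and individual value.

## Worked example

The bundled six-class fixture (`Procedure` and `Cosmetic procedure` under a
root; `Administrative procedure` under `Procedure`;
`Death administrative procedure` and `Biopsy administration` under that):

```sh
python examples/worked_example.py
```

```text
classes: 6, subclass edges: 5
LR class 'administrative procedure': exhibited by 1 other class(es)
LR class 'procedure': exhibited by 3 other class(es)
LSLD global value: 0.750 (3 positive / 1 negative)
systematic naming global value: 0.600 (3 positive / 2 negative)
  'administrative procedure': value=0.500 over 2 descendants
  'procedure': value=0.667 over 3 descendants
```

LSLD is 3/4 because of the four classes lexically pointing at an LR class,
only `Cosmetic procedure` has no axiomatic path to `Procedure`. Systematic
naming is 3/5 because `Biopsy administration` drops its ancestors' label
fragment under both LR classes — precisely the kind of naming break the
audit is meant to surface.

Other examples: `examples/readability_report.py`,
`examples/synthetic_recovery.py`, `examples/audit_bundle.py`.

## Command line

```sh
ontoaudit audit release1.owl release2.owl --out reports \
    --coverage 0.001 --strip-semantic-tag --metrics readability,lsld,sysnaming
```

writes, per input: `readability.csv`, `lr_classes.csv`, `lsld_report.csv`,
`sysnaming_report.csv`, `hierarchy_lsld.csv`, `hierarchy_sysnaming.csv`,
`negative_cases_{lsld,sysnaming}.csv` and `summary.json`, plus one
`longitudinal.csv` of global values across inputs. Exit status 2 flags
partially failed runs. `--strip-semantic-tag` removes the trailing
parenthesized category of SNOMED fully specified names before tokenizing.

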