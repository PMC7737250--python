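"""Label normalization and lexical-regularity (LR) class detection.

A *lexical regularity* is a token pattern that recurs across class labels;
an *LR class* is a class whose full normalized label is itself such a
pattern.  Mining is anchored on class labels: a pattern is a candidate iff
it is some class's complete label, because both structural-accuracy metrics
only ever use the regularities attached to LR classes.  A frequent fragment
that is nobody's full label (e.g. "administrative" alone) is therefore never
an LR class.

Matching is exact contiguous containment at token granularity: the pattern
must appear as an unbroken run of whole tokens inside the label.  Gapped or
fuzzy matches do not count, so "Poisoning caused by herbal asthma mixture of
undetermined intent" does *not* exhibit "Poisoning of undetermined intent".
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

from .io import RDFS_LABEL
from .model import OntologyGraph

logger = logging.getLogger(__name__)

_SEMANTIC_TAG = re.compile(r"\s*\([^()]*\)\s*$")

Tokens = tuple[str, ...]


@dataclass(frozen=True)
class LexConfig:
    """Tokenization and detection settings.

    ``coverage`` is the fraction of ontology classes whose labels must
    exhibit a pattern for it to count as a regularity; a candidate needs
    support >= ceil(coverage * n_classes).  The default, 0.001 (0.1%), is
    deliberately permissive: large terminologies carry meaningful
    regularities at sub-percent support.  ``strip_semantic_tag`` removes one
    trailing parenthesized category, as in SNOMED fully specified names
    ("Open wound (disorder)" -> "open wound").
    """

    token_delimiter: str = " "
    case_mode: str = "insensitive"  # or "sensitive"
    coverage: float = 0.001
    strip_semantic_tag: bool = False
    label_property: str = RDFS_LABEL

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError(f"coverage must be in (0, 1], got {self.coverage}")
        if self.case_mode not in ("insensitive", "sensitive"):
            raise ValueError(f"case_mode must be insensitive|sensitive, got {self.case_mode}")


@dataclass(frozen=True)
class LRClass:
    """A class whose full normalized label is a lexical regularity.

    ``support`` counts the distinct classes exhibiting the regularity,
    excluding every class whose full label equals it (so an LR class never
    supports itself, nor does a duplicate-labelled twin).
    """

    class_iri: str
    regularity: Tokens
    support: int

    @property
    def label(self) -> str:
        return " ".join(self.regularity)


def normalize_label(raw: str, cfg: LexConfig = LexConfig()) -> Tokens:
    """Normalize a label to its token sequence.

    Optionally strips one trailing parenthesized semantic tag, case-folds
    in insensitive mode, splits on the delimiter and drops empty tokens.
    An empty result (e.g. a label that was only a semantic tag) is returned
    as the empty tuple; callers exclude such labels from analysis.
    """
    if not raw:
        raise ValueError("label must be non-empty")
    text = raw
    if cfg.strip_semantic_tag:
        text = _SEMANTIC_TAG.sub("", text, count=1)
    if cfg.case_mode == "insensitive":
        text = text.casefold()
    return tuple(t for t in text.split(cfg.token_delimiter) if t)


def exhibits(label_tokens: Tokens, lr_tokens: Tokens) -> bool:
    """True iff ``lr_tokens`` occurs as a contiguous run inside ``label_tokens``.

    Token boundaries are respected: "oral" never matches inside "temporal".
    """
    if not label_tokens or not lr_tokens:
        raise ValueError("token sequences must be non-empty")
    k = len(lr_tokens)
    if k > len(label_tokens):
        return False
    return any(label_tokens[i:i + k] == lr_tokens
               for i in range(len(label_tokens) - k + 1))


def canonical_labels(graph: OntologyGraph,
                     cfg: LexConfig = LexConfig()) -> dict[str, Tokens]:
    """Normalized canonical label per class.

    When a class asserts several values for the label property the
    lexicographically smallest is taken, for determinism.  Unlabelled
    classes and labels empty after normalization are excluded with a
    logged warning.
    """
    labels: dict[str, Tokens] = {}
    skipped = 0
    for cls in graph.classes:
        values = graph.labels_of(cls, cfg.label_property)
        if not values:
            skipped += 1
            continue
        tokens = normalize_label(values[0], cfg)
        if not tokens:
            logger.warning("label of %s is empty after normalization; excluded", cls)
            continue
        labels[cls] = tokens
    if skipped:
        logger.warning("%d classes without %s label excluded from lexical analysis",
                       skipped, cfg.label_property)
    return labels


def support_threshold(graph: OntologyGraph, cfg: LexConfig) -> int:
    return max(1, math.ceil(cfg.coverage * len(graph.classes)))


def detect_lr_classes(graph: OntologyGraph,
                      cfg: LexConfig = LexConfig(),
                      labels: dict[str, Tokens] | None = None) -> list[LRClass]:
    """Detect every LR class at the configured coverage threshold.

    For each full class label L, the support of L is the number of classes
    whose labels exhibit L, excluding all classes labelled exactly L.  Every
    class labelled L becomes a distinct :class:`LRClass` when support clears
    ceil(coverage * n_classes) — duplicate labels yield one record per
    class, sharing the regularity.  Results are sorted by class IRI.
    """
    if labels is None:
        labels = canonical_labels(graph, cfg)
    if not labels:
        logger.warning("no labelled classes; no lexical regularities detected")
        return []
    threshold = support_threshold(graph, cfg)

    # inverted index: token -> classes whose label contains it
    by_token: dict[str, set[str]] = {}
    for cls, tokens in labels.items():
        for tok in set(tokens):
            by_token.setdefault(tok, set()).add(cls)

    candidates: dict[Tokens, list[str]] = {}
    for cls, tokens in labels.items():
        candidates.setdefault(tokens, []).append(cls)

    result: list[LRClass] = []
    for pattern, owners in candidates.items():
        pool = set.intersection(*(by_token[t] for t in set(pattern)))
        support = sum(
            1 for cls in pool
            if labels[cls] != pattern and exhibits(labels[cls], pattern)
        )
        if support >= threshold:
            result.extend(LRClass(cls, pattern, support) for cls in owners)
    result.sort(key=lambda lr: lr.class_iri)
    return result
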