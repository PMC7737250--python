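"""Audit configuration: YAML config file handling.

A config file may carry any of the blocks below; everything is optional and
defaults apply::

    annotation_catalog:
      names: [http://...]
      synonyms: [http://...]
      descriptions: [http://...]
    lexreg:
      coverage: 0.001          # fraction of classes, NOT a percentage
      case_mode: insensitive
      strip_semantic_tag: false
      token_delimiter: " "
      label_property: http://www.w3.org/2000/01/rdf-schema#label
    root: http://snomed.info/id/138875005
    metrics: [readability, lsld, sysnaming]
    wilcoxon_method: paired    # or "unpaired"

Note on ``coverage``: it is a fraction in (0, 1].  A value of 0.1 means ten
percent of the ontology classes must exhibit a pattern — for large
terminologies the useful regularities sit well below that, hence the
default of 0.001 (0.1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .lexreg import LexConfig
from .readability import AnnotationCatalog

ALL_METRICS = ("readability", "lsld", "sysnaming")


@dataclass(frozen=True)
class AuditConfig:
    catalog: AnnotationCatalog = field(default_factory=AnnotationCatalog)
    lex: LexConfig = field(default_factory=LexConfig)
    root: str | None = None
    metrics: tuple[str, ...] = ALL_METRICS
    wilcoxon_method: str = "paired"


def load_config(path: str | Path | None) -> AuditConfig:
    """Load an :class:`AuditConfig` from YAML; ``None`` yields the defaults."""
    if path is None:
        return AuditConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_mapping(data)


def config_from_mapping(data: dict) -> AuditConfig:
    catalog = AnnotationCatalog()
    if "annotation_catalog" in data:
        block = data["annotation_catalog"]
        catalog = AnnotationCatalog(
            name_properties=frozenset(block.get("names", catalog.name_properties)),
            synonym_properties=frozenset(block.get("synonyms", catalog.synonym_properties)),
            description_properties=frozenset(
                block.get("descriptions", catalog.description_properties)),
        )
    lex = LexConfig()
    if "lexreg" in data:
        block = dict(data["lexreg"])
        known = {"token_delimiter", "case_mode", "coverage",
                 "strip_semantic_tag", "label_property"}
        unknown = set(block) - known
        if unknown:
            raise ValueError(f"unknown lexreg option(s): {sorted(unknown)}")
        lex = replace(lex, **block)
    metrics = tuple(data.get("metrics", ALL_METRICS))
    bad = set(metrics) - set(ALL_METRICS)
    if bad:
        raise ValueError(f"unknown metric(s): {sorted(bad)}")
    return AuditConfig(
        catalog=catalog,
        lex=lex,
        root=data.get("root"),
        metrics=metrics,
        wilcoxon_method=data.get("wilcoxon_method", "paired"),
    )
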