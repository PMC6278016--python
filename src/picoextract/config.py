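"""YAML configuration loading.

One file governs the whole pipeline: lexicon paths, CRF settings, rule
thresholds and the repetition count.  Every constant has the package default
as fallback, so a partial (or absent) file is fine.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .crf_stage import CRFConfig
from .pipeline import PipelineConfig
from .preprocess import DEFAULT_HEADER_MAP, HeaderMap
from .rbm_stage import RuleThresholds
from .semantic_tagger import LexiconBundle, default_bundle, load_bundle


def load_config(path: str | Path | None = None) -> tuple[PipelineConfig, LexiconBundle, HeaderMap]:
    """Read a YAML config; returns (pipeline config, lexicons, header map)."""
    doc: dict = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    crf = CRFConfig(**doc.get("crf", {}))
    thresholds = RuleThresholds(**doc.get("rbm", {}))
    pipeline = PipelineConfig(
        crf=crf,
        thresholds=thresholds,
        use_rbm=doc.get("use_rbm", True),
        reps=doc.get("reps"),
    )
    if "lexicons" in doc:
        bundle = load_bundle(doc["lexicons"])
    else:
        bundle = default_bundle()
    if "header_map" in doc:
        header_map = HeaderMap.from_csv(doc["header_map"])
    else:
        header_map = DEFAULT_HEADER_MAP
    return pipeline, bundle, header_map


def generator_spec_from_yaml(path: str | Path | None = None, **overrides):
    from .synthetic_data import GeneratorSpec

    doc: dict = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    doc.update(overrides)
    if "sentences_per_abstract" in doc:
        doc["sentences_per_abstract"] = tuple(doc["sentences_per_abstract"])
    if "sentence_length" in doc:
        doc["sentence_length"] = tuple(doc["sentence_length"])
    return GeneratorSpec(**doc)
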