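"""End-to-end orchestration of the two-stage hybrid extraction.

Stage 1 (statistical, coarse-grained): preprocess, extract features, decode
with the repetition scheme, then pick one sentence per PICO element with the
weighted scorer.  Stage 2 (rules, fine-grained): for abstracts where stage 1
returned no Population or Intervention sentence at all, the feature-threshold
rules propose one.  Stage 2 only ever fills gaps — it cannot override a
stage-1 selection — so combined recall can only match or exceed the
statistical stage's.

Training-side preparation differs from test-side on purpose: unstructured
training abstracts are pseudo-structured (headers fabricated from gold
labels) so the structural features carry signal, while unstructured test
abstracts keep NOHEADING — gold labels are obviously unavailable at test
time, and the statistical stage's weakness there is precisely what the rule
stage compensates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .corpus_io import (
    AbstractRecord,
    LabeledCorpus,
    PICO_ELEMENTS,
    copy_abstract,
)
from .crf_stage import CRFConfig, TrainedModel, predict_with_repetition, train
from .evaluation import EvalReport, evaluate_abstract_level, evaluate_sentence_level
from .features import extract_corpus_features
from .preprocess import DEFAULT_HEADER_MAP, HeaderMap, pseudo_structure, standardize_corpus_headers
from .rbm_stage import DEFAULT_THRESHOLDS, RBM_ELEMENTS, RuleThresholds, apply_rbm
from .selection import score_abstract_candidates, select_best
from .semantic_tagger import LexiconBundle, default_bundle


@dataclass
class PipelineConfig:
    crf: CRFConfig = field(default_factory=CRFConfig)
    thresholds: RuleThresholds = field(default_factory=RuleThresholds)
    use_rbm: bool = True
    reps: int | None = None  # None -> crf.test_repetitions


@dataclass
class AbstractExtraction:
    abstract_id: str
    mlm: dict[str, int | None]
    combined: dict[str, int | None]
    candidates: list[set[str]]
    scores: dict[str, dict[int, "SelectionScore"]]  # noqa: F821 — selection module


@dataclass
class HybridResult:
    extractions: list[AbstractExtraction]
    mlm_report: EvalReport
    combined_report: EvalReport
    rbm_on_missed_report: EvalReport | None
    sentence_report: EvalReport
    counts: dict

    def selections(self, stage: str = "combined") -> dict[str, dict[str, int | None]]:
        return {
            e.abstract_id: (e.combined if stage == "combined" else e.mlm)
            for e in self.extractions
        }


def prepare_training_corpus(
    corpus: LabeledCorpus, header_map: HeaderMap = DEFAULT_HEADER_MAP
) -> LabeledCorpus:
    """Standardize headers and pseudo-structure unstructured abstracts."""
    out = []
    for abstract in corpus.abstracts:
        if abstract.is_structured:
            out.append(standardize_corpus_headers(abstract, header_map))
        else:
            out.append(pseudo_structure(abstract))
    return LabeledCorpus(abstracts=out, provenance=corpus.provenance)


def prepare_test_corpus(
    corpus: LabeledCorpus, header_map: HeaderMap = DEFAULT_HEADER_MAP
) -> LabeledCorpus:
    """Standardize headers only; unstructured abstracts keep NOHEADING."""
    return LabeledCorpus(
        abstracts=[standardize_corpus_headers(a, header_map) for a in corpus.abstracts],
        provenance=corpus.provenance,
    )


def train_pipeline(
    train_corpus: LabeledCorpus,
    config: PipelineConfig | None = None,
    bundle: LexiconBundle | None = None,
    header_map: HeaderMap = DEFAULT_HEADER_MAP,
) -> TrainedModel:
    config = config or PipelineConfig()
    bundle = bundle or default_bundle()
    prepared = prepare_training_corpus(train_corpus, header_map)
    vectors = extract_corpus_features(prepared, bundle)
    return train(prepared, vectors, config.crf)


def extract_abstract(
    model: TrainedModel,
    abstract: AbstractRecord,
    vectors,
    config: PipelineConfig,
) -> AbstractExtraction:
    """Run both stages on one preprocessed abstract."""
    reps = config.reps if config.reps is not None else model.config.test_repetitions
    candidates = predict_with_repetition(model, abstract, vectors, reps)
    scores = score_abstract_candidates(abstract, vectors, candidates)
    mlm: dict[str, int | None] = {}
    for element in PICO_ELEMENTS:
        chosen = select_best(element, abstract, scores[element])
        mlm[element] = None if chosen is None else chosen.index
    combined = dict(mlm)
    if config.use_rbm:
        missed = [e for e in RBM_ELEMENTS if mlm[e] is None]
        if missed:
            filled = apply_rbm(abstract, missed, vectors, config.thresholds)
            for element, hit in filled.items():
                if hit is not None:
                    combined[element] = hit[0].index
    return AbstractExtraction(
        abstract_id=abstract.abstract_id,
        mlm=mlm,
        combined=combined,
        candidates=candidates,
        scores=scores,
    )


def run_hybrid(
    train_corpus: LabeledCorpus,
    test_corpus: LabeledCorpus,
    config: PipelineConfig | None = None,
    bundle: LexiconBundle | None = None,
    model: TrainedModel | None = None,
    header_map: HeaderMap = DEFAULT_HEADER_MAP,
) -> HybridResult:
    """Train (unless a model is supplied), extract, and evaluate.

    Produces statistical-only, combined, and rules-on-missed-abstracts
    reports plus per-stage accounting (how many misses each stage left, and
    whether rule fills landed on structured or unstructured abstracts).
    """
    config = config or PipelineConfig()
    bundle = bundle or default_bundle()
    if model is None:
        model = train_pipeline(train_corpus, config, bundle, header_map)
    prepared = prepare_test_corpus(test_corpus, header_map)
    vectors = extract_corpus_features(prepared, bundle)
    extractions = [
        extract_abstract(model, abstract, vectors, config)
        for abstract in prepared.abstracts
    ]
    predictions = {}
    for abstract, ext in zip(prepared.abstracts, extractions):
        for sentence, cands in zip(abstract.sentences, ext.candidates):
            predictions[(abstract.abstract_id, sentence.index)] = cands
    mlm_sel = {e.abstract_id: e.mlm for e in extractions}
    comb_sel = {e.abstract_id: e.combined for e in extractions}
    mlm_report = evaluate_abstract_level(mlm_sel, prepared)
    combined_report = evaluate_abstract_level(comb_sel, prepared)
    sentence_report = evaluate_sentence_level(predictions, prepared)

    # Rules judged on the abstracts the statistical stage missed only.
    rbm_report = None
    counts: dict = {"n_abstracts": len(prepared.abstracts)}
    if config.use_rbm:
        by_id = {a.abstract_id: a for a in prepared.abstracts}
        missed_ids = {
            e: [x.abstract_id for x in extractions if x.mlm[e] is None]
            for e in RBM_ELEMENTS
        }
        rbm_sel = {}
        accounting = {}
        for element in RBM_ELEMENTS:
            filled_structured = filled_unstructured = not_applicable = 0
            for aid in missed_ids[element]:
                ext = next(x for x in extractions if x.abstract_id == aid)
                rbm_sel.setdefault(aid, {})[element] = ext.combined[element]
                if ext.combined[element] is None:
                    not_applicable += 1
                elif by_id[aid].is_structured:
                    filled_structured += 1
                else:
                    filled_unstructured += 1
            accounting[element] = {
                "missed_by_mlm": len(missed_ids[element]),
                "rule_filled_structured": filled_structured,
                "rule_filled_unstructured": filled_unstructured,
                "not_applicable": not_applicable,
            }
        missed_union = sorted({aid for ids in missed_ids.values() for aid in ids})
        if missed_union:
            missed_corpus = LabeledCorpus(
                abstracts=[copy_abstract(by_id[aid]) for aid in missed_union]
            )
            rbm_report = evaluate_abstract_level(
                {aid: rbm_sel.get(aid, {}) for aid in missed_union},
                missed_corpus,
                elements=RBM_ELEMENTS,
            )
        counts["rbm"] = accounting
    return HybridResult(
        extractions=extractions,
        mlm_report=mlm_report,
        combined_report=combined_report,
        rbm_on_missed_report=rbm_report,
        sentence_report=sentence_report,
        counts=counts,
    )


def result_to_json(result: HybridResult) -> str:
    """Stable JSON rendering of selections and reports (for manifests and
    byte-level reproducibility checks)."""
    doc = {
        "extractions": [
            {
                "abstract_id": e.abstract_id,
                "mlm": {k: e.mlm[k] for k in sorted(e.mlm)},
                "combined": {k: e.combined[k] for k in sorted(e.combined)},
                "candidates": [sorted(c) for c in e.candidates],
            }
            for e in result.extractions
        ],
        "mlm_report": result.mlm_report.to_dict(),
        "combined_report": result.combined_report.to_dict(),
        "rbm_on_missed_report": (
            None
            if result.rbm_on_missed_report is None
            else result.rbm_on_missed_report.to_dict()
        ),
        "sentence_report": result.sentence_report.to_dict(),
        "counts": result.counts,
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def write_manifest(path: str | Path, config: PipelineConfig, seed: int, extra: dict | None = None) -> Path:
    """Write the config+seed manifest sufficient to reproduce a run."""
    from dataclasses import asdict

    doc = {
        "seed": seed,
        "crf": asdict(config.crf),
        "thresholds": asdict(config.thresholds),
        "use_rbm": config.use_rbm,
        "reps": config.reps,
    }
    if extra:
        doc.update(extra)
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path
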